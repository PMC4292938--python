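"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_probe_intensities` — probe-level arrays under the
  convolution noise model (normal background plus exponential signal), with
  per-sample exon-skipping fractions ``psi`` attenuating the signal mean of
  target-exon probes by ``(1 - psi)``;
* :func:`simulate_index_cohort` — per-sample index values for a two-group
  cohort parameterized directly by the group means and standard errors, with
  the group SD recovered as ``SE * sqrt(n)``;
* :func:`simulate_antibody_array` — duplicate-spot antibody arrays with
  blanks and controls and known injected group effects.

All draws are reproducible: every generator takes a seed, and independent
child streams are spawned per component so adding one stage never perturbs
another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fixtures import load_probe_alignments

__all__ = [
    "SkipFractionModel",
    "ProbeDesign",
    "CohortSpec",
    "ProbeLevelDataset",
    "simulate_probe_intensities",
    "sd_from_se",
    "simulate_index_cohort",
    "AntibodyArrayDataset",
    "simulate_antibody_array",
    "default_cohort_spec",
]

REFERENCE_GROUP = "reference"
CASE_GROUP = "case"


@dataclass(frozen=True)
class SkipFractionModel:
    """Distribution of the per-sample exon-skipping fraction psi in [0, 1].

    ``kind="fixed"`` puts all mass at ``mean``; ``kind="beta"`` draws from a
    Beta with the given mean and concentration (a+b).
    """

    kind: str = "fixed"
    mean: float = 0.0
    concentration: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "beta"):
            raise ValueError(f"unknown skip-fraction model {self.kind!r}")
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"psi mean must be in [0, 1], got {self.mean}")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed" or self.mean in (0.0, 1.0):
            return np.full(n, self.mean)
        a = self.mean * self.concentration
        b = (1.0 - self.mean) * self.concentration
        return rng.beta(a, b, size=n)


@dataclass(frozen=True)
class ProbeDesign:
    """Probe layout of a simulated chip.

    ``is_target`` marks the probes interrogating the skipped exon;
    ``exon_labels`` may be None for probes without an alignment record
    (they exist on the chip and enter median centering only).
    """

    probe_ids: tuple[str, ...]
    probeset_ids: tuple[str, ...]
    is_target: tuple[bool, ...]
    exon_labels: tuple = ()

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if len(self.probeset_ids) != n or len(self.is_target) != n:
            raise ValueError("probe design fields must have equal length")
        if len(set(self.probe_ids)) != n:
            raise ValueError("probe ids must be unique")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a simulated two-group probe-level cohort.

    Intensity model, per probe p and sample s:

        I(p, s) = array_scale_s * [ N(background_mean, background_sd^2)
                                    + Exp(mean = signal_scale * phi_p * a(p, s)) ]

    with ``a(p, s) = 1 - psi_s`` for target-exon probes and 1 otherwise,
    clipped at zero (raw scanner intensities are non-negative).
    """

    n_reference: int
    n_case: int
    skip_fraction_reference: SkipFractionModel
    skip_fraction_case: SkipFractionModel
    probes: ProbeDesign
    probe_affinities: tuple[float, ...]
    background_mean: float = 100.0
    background_sd: float = 10.0
    signal_scale: float = 1000.0
    array_scale: float | tuple[float, ...] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference < 1 or self.n_case < 1:
            raise ValueError("need at least one sample per group")
        if len(self.probe_affinities) != self.probes.n_probes:
            raise ValueError("probe_affinities must match the probe design")
        if min(self.probe_affinities) <= 0:
            raise ValueError("probe affinities must be strictly positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.signal_scale <= 0:
            raise ValueError("signal_scale must be > 0")
        scales = np.atleast_1d(np.asarray(self.array_scale, dtype=float))
        if (scales <= 0).any():
            raise ValueError("array scales must be strictly positive")
        n = self.n_reference + self.n_case
        if scales.size not in (1, n):
            raise ValueError("array_scale must be scalar or one value per sample")

    @property
    def n_samples(self) -> int:
        return self.n_reference + self.n_case


@dataclass
class ProbeLevelDataset:
    """Probe x sample intensities plus annotations and simulation truth."""

    intensities: pd.DataFrame  # probes x samples
    probeset_ids: pd.Series  # per probe
    group_labels: pd.Series  # per sample
    truth: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns


def simulate_probe_intensities(spec: CohortSpec) -> ProbeLevelDataset:
    """Draw a probe-level dataset under the convolution noise model."""
    ss = np.random.SeedSequence(spec.seed)
    rng_psi, rng_bg, rng_sig = (np.random.default_rng(s) for s in ss.spawn(3))

    n_ref, n_case = spec.n_reference, spec.n_case
    psi = np.concatenate(
        [
            spec.skip_fraction_reference.draw(rng_psi, n_ref),
            spec.skip_fraction_case.draw(rng_psi, n_case),
        ]
    )
    groups = np.array([REFERENCE_GROUP] * n_ref + [CASE_GROUP] * n_case)

    phi = np.asarray(spec.probe_affinities, dtype=float)
    is_target = np.asarray(spec.probes.is_target, dtype=bool)
    atten = np.ones((spec.probes.n_probes, spec.n_samples))
    atten[is_target, :] = 1.0 - psi[None, :]

    mean_signal = spec.signal_scale * phi[:, None] * atten
    signal = rng_sig.exponential(scale=mean_signal)
    if spec.background_sd > 0:
        background = rng_bg.normal(spec.background_mean, spec.background_sd, signal.shape)
    else:
        background = np.full(signal.shape, spec.background_mean)
    scales = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.array_scale, dtype=float)), (spec.n_samples,)
    )
    intensities = np.maximum(scales[None, :] * (background + signal), 0.0)

    sample_ids = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    df = pd.DataFrame(intensities, index=list(spec.probes.probe_ids), columns=sample_ids)
    return ProbeLevelDataset(
        intensities=df,
        probeset_ids=pd.Series(list(spec.probes.probeset_ids), index=df.index),
        group_labels=pd.Series(groups, index=sample_ids, name="group"),
        truth={
            "psi": pd.Series(psi, index=sample_ids, name="psi"),
            "is_target": pd.Series(is_target, index=df.index, name="is_target"),
            "expected_signal_mean": pd.DataFrame(
                mean_signal, index=df.index, columns=sample_ids
            ),
        },
    )


def sd_from_se(se: float, n: int) -> float:
    """Recover a group standard deviation from its standard error: SE * sqrt(n)."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2")
    return se * float(np.sqrt(n))


def simulate_index_cohort(
    n_reference: int,
    mean_reference: float,
    se_reference: float,
    n_case: int,
    mean_case: float,
    se_case: float,
    seed: int | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Draw per-sample index values for a two-group cohort.

    Group values are ``Normal(mean, (se * sqrt(n))^2)`` — the published
    cohort summaries report the group mean and its standard error, so the
    sample-level spread is recovered as ``SE * sqrt(n)``.

    Returns the reference and case vectors as labeled Series.
    """
    for n in (n_reference, n_case):
        if n < 2:
            raise ValueError("each group needs n >= 2")
    ss = np.random.SeedSequence(seed)
    rng_ref, rng_case = (np.random.default_rng(s) for s in ss.spawn(2))
    ref = rng_ref.normal(mean_reference, sd_from_se(se_reference, n_reference), n_reference)
    case = rng_case.normal(mean_case, sd_from_se(se_case, n_case), n_case)
    ref_s = pd.Series(ref, index=[f"R{i + 1:04d}" for i in range(n_reference)], name=REFERENCE_GROUP)
    case_s = pd.Series(case, index=[f"C{i + 1:04d}" for i in range(n_case)], name=CASE_GROUP)
    return ref_s, case_s


@dataclass
class AntibodyArrayDataset:
    """Spot-level antibody array data for a two-group experiment.

    ``spots`` has one row per physical spot with columns: sample_id, group,
    antibody_id (None for control spots), spot_type (antibody / blank /
    negative / positive), replicate, intensity.
    """

    spots: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_antibody_array(
    n_antibodies: int = 1318,
    n_replicates_per_spot: int = 2,
    group_effects=None,
    noise_sd: float = 0.0,
    n_reference: int = 4,
    n_case: int = 4,
    seed: int | None = None,
    n_blanks: int = 4,
    n_negative: int = 4,
    n_positive: int = 2,
) -> AntibodyArrayDataset:
    """Simulate duplicate-spot antibody arrays with blanks and controls.

    ``group_effects`` maps antibody index (or id) to a log10 fold effect
    applied to case samples.  Spot intensity for antibody a on sample s is

        blank_level + array_scale_s * abundance_a * 10**(effect_a * case_s)
                    * 10**Normal(0, noise_sd)

    so with ``noise_sd=0`` the normalized pipeline output is exactly the
    injected effect structure.  Blank spots carry ``blank_level`` exactly.
    """
    if n_antibodies < 1 or n_replicates_per_spot < 1:
        raise ValueError("counts must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ss = np.random.SeedSequence(seed)
    rng_base, rng_scale, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    antibody_ids = [f"AB{i + 1:05d}" for i in range(n_antibodies)]
    effects = np.zeros(n_antibodies)
    if group_effects:
        for key, eff in dict(group_effects).items():
            idx = antibody_ids.index(key) if isinstance(key, str) else int(key)
            effects[idx] = float(eff)

    abundance = 10.0 ** rng_base.normal(3.0, 0.4, n_antibodies)
    blank_level = 50.0
    n_samples = n_reference + n_case
    sample_ids = [f"A{i + 1:03d}" for i in range(n_samples)]
    groups = [REFERENCE_GROUP] * n_reference + [CASE_GROUP] * n_case
    array_scale = 10.0 ** rng_scale.normal(0.0, 0.1, n_samples)

    rows = []
    for s_idx, (sid, grp) in enumerate(zip(sample_ids, groups)):
        is_case = 1.0 if grp == CASE_GROUP else 0.0
        level = abundance * 10.0 ** (effects * is_case)
        for rep in range(n_replicates_per_spot):
            noise = (
                10.0 ** rng_noise.normal(0.0, noise_sd, n_antibodies)
                if noise_sd > 0
                else np.ones(n_antibodies)
            )
            vals = blank_level + array_scale[s_idx] * level * noise
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "group": grp,
                        "antibody_id": antibody_ids,
                        "spot_type": "antibody",
                        "replicate": rep + 1,
                        "intensity": vals,
                    }
                )
            )
        control_specs = [
            ("blank", n_blanks, blank_level),
            ("negative", n_negative, blank_level),
            ("positive", n_positive, blank_level + array_scale[s_idx] * 5e4),
        ]
        for spot_type, count, value in control_specs:
            if count:
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": sid,
                            "group": grp,
                            "antibody_id": None,
                            "spot_type": spot_type,
                            "replicate": np.arange(1, count + 1),
                            "intensity": value,
                        }
                    )
                )
    spots = pd.concat(rows, ignore_index=True)
    return AntibodyArrayDataset(
        spots=spots,
        truth={
            "effects_log10": pd.Series(effects, index=antibody_ids),
            "array_scale": pd.Series(array_scale, index=sample_ids),
        },
    )


# --- calibrated default preset -------------------------------------------------

#: Reference-group mean index the preset is calibrated to.
_CAL_REFERENCE_INDEX = 0.52
#: Case-group mean index the preset is calibrated to.
_CAL_CASE_INDEX = -0.15


def default_cohort_spec(
    n_reference: int = 74,
    n_case: int = 279,
    seed: int = 0,
    n_filler_probesets: int = 40,
) -> CohortSpec:
    """The calibrated default cohort.

    Probe layout: the ten aligned probes of the CD22 exon 10-14 probeset
    (three on exon 12, seven flanking) plus one unaligned eleventh probe,
    and ``n_filler_probesets`` background probesets of ten probes each so
    quantile normalization sees a realistic intensity distribution.

    Calibration: on the log2 scale the index of a sample with skipping
    fraction psi is, in expectation,

        mean(log2 phi_target) - mean(log2 phi_flank) + log2(1 - psi),

    so target-probe affinities of ``2**0.52`` (flanking = 1) put the
    no-skipping reference mean at 0.52, and a case psi centred at 0.372
    (log2(0.628) = -0.67) puts the case mean at -0.15 — the published group
    means.  Cohort sizes default to the published 74 reference / 279 case
    samples.
    """
    records = load_probe_alignments()
    target_exon = "Exon 12"
    probe_ids = [r.probe_id for r in records] + ["HG-U133_PLUS_2:217422_S_AT_X"]
    probeset_ids = ["217422_s_at"] * len(probe_ids)
    is_target = [r.exon_label == target_exon for r in records] + [False]
    exon_labels = [r.exon_label for r in records] + [None]
    affinities = [2.0**_CAL_REFERENCE_INDEX if t else 1.0 for t in is_target]

    # background probesets: fixed internal stream so the preset is a constant
    rng = np.random.default_rng(np.random.SeedSequence(entropy=991114))
    for k in range(n_filler_probesets):
        for p in range(10):
            probe_ids.append(f"FILLER_{k + 1:03d}_AT_{p + 1}")
            probeset_ids.append(f"filler_{k + 1:03d}_at")
            is_target.append(False)
            exon_labels.append(None)
            affinities.append(float(np.exp(rng.normal(0.0, 0.5))))

    probes = ProbeDesign(
        probe_ids=tuple(probe_ids),
        probeset_ids=tuple(probeset_ids),
        is_target=tuple(is_target),
        exon_labels=tuple(exon_labels),
    )
    psi_case_mean = 1.0 - 2.0 ** (_CAL_CASE_INDEX - _CAL_REFERENCE_INDEX)  # 0.372
    return CohortSpec(
        n_reference=n_reference,
        n_case=n_case,
        skip_fraction_reference=SkipFractionModel(kind="fixed", mean=0.0),
        skip_fraction_case=SkipFractionModel(
            kind="beta", mean=psi_case_mean, concentration=200.0
        ),
        probes=probes,
        probe_affinities=tuple(affinities),
        background_mean=100.0,
        background_sd=10.0,
        signal_scale=1000.0,
        array_scale=1.0,
        seed=seed,
    )
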