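"""Synthetic cohorts and multi-omics data with planted, strain-opposite signals.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without the deposited data sets:

* behavioral cohorts — defeated mice drawn from a susceptible/resilient
  mixture of log-normal SI-ratio distributions, controls from the control
  distribution, with interaction-zone times back-computed so the SI ratio
  of a record reproduces the drawn value;
* sequencing counts — negative-binomial with log-normally drawn gene-wise
  baseline means, per-sample library-size factors, additive (log-scale)
  batch shifts, and planted gene-set effects whose sign flips between
  strains;
* proteomics — log-normal heavy/light ratios against a pooled reference
  with 3 technical replicates per sample and per-protein replicate
  variability, so the protein inclusion filter has work to do;
* miRNA-target interaction tables with per-pair evidence-source counts.

Determinism contract: identical spec + seed give bit-identical outputs;
each operation derives its own substream from the spec's global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .types import BehavioralRecord, OmicsMatrix, TRIAL_LENGTH_S

__all__ = [
    "StrainCohort",
    "CohortSpec",
    "SignalSpec",
    "ProteomicsDataset",
    "simulate_cohort",
    "simulate_counts",
    "simulate_proteomics",
    "simulate_interactions",
    "make_sample_meta",
]

# substream tags so each operation has an independent, reproducible stream
_TAG_COHORT, _TAG_COUNTS, _TAG_PROTEO, _TAG_INTER = 11, 12, 13, 14


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class StrainCohort:
    """Per-strain cohort parameters.

    ``control_log_mean``/``control_log_sd`` parameterize the natural-log SI
    ratio (percent scale) of controls; the classification border they imply
    is exp(mean - sd).
    """

    n_control: int
    n_defeated: int
    susceptible_fraction: float
    control_log_mean: float
    control_log_sd: float

    def validate(self) -> None:
        if self.n_control < 0 or self.n_defeated < 0:
            raise InvalidSpecError("sample sizes must be >= 0")
        if not (0.0 <= self.susceptible_fraction <= 1.0):
            raise InvalidSpecError("susceptible_fraction must be in [0, 1]")
        if self.control_log_sd <= 0:
            raise InvalidSpecError("control_log_sd must be > 0")
        if self.susceptible_fraction > 0 and self.n_defeated <= 0:
            raise InvalidSpecError(
                "positive susceptible fraction requires a positive defeated sample size"
            )


# Defaults encode the two-strain study design: the resilient-leaning B6
# strain (34 susceptible / 78 resilient of 112 defeated, 30%) and the
# susceptible-leaning D2 strain (62 / 8 of 70, 89%), 56 controls each.
# Control log-scale parameters are anchored so that the implied borders
# exp(mean - sd) match the reported strain borders 76.49 (B6) and 105.99 (D2).
def _default_strains() -> dict[str, StrainCohort]:
    return {
        "B6": StrainCohort(56, 112, 34 / 112, np.log(76.49) + 0.27, 0.27),
        "D2": StrainCohort(56, 70, 62 / 70, np.log(105.99) + 0.27, 0.27),
    }


@dataclass
class CohortSpec:
    """Specification of a simulated two-strain behavioral cohort.

    ``susceptible_offset``/``resilient_offset`` shift the log SI ratio of the
    two defeated subpopulations relative to the control mean. The defaults
    place susceptible mice ~3.7 control SDs below the control mean and
    resilient mice ~1.1 SDs above it, i.e. clearly on either side of the
    mean-minus-one-SD border so that the mixture weight is recoverable.
    """

    strains: dict[str, StrainCohort] = field(default_factory=_default_strains)
    susceptible_offset: float = -1.0
    resilient_offset: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not self.strains:
            raise InvalidSpecError("at least one strain required")
        for cohort in self.strains.values():
            cohort.validate()


def simulate_cohort(spec: CohortSpec) -> list[BehavioralRecord]:
    """Draw a behavioral cohort of control and defeated mice.

    Defeated mice are a mixture of the susceptible and resilient SI-ratio
    distributions at the specified fraction. Interaction-zone times are
    reconstructed from the drawn ratio with a 30 s no-target time (scaled
    down if the target time would exceed the 150 s trial length), so
    ``compute_si_ratio`` reproduces the drawn ratio exactly.
    """
    spec.validate()
    rng = _rng(spec.seed, _TAG_COHORT)
    records: list[BehavioralRecord] = []
    for strain, cohort in sorted(spec.strains.items()):
        mu, sd = cohort.control_log_mean, cohort.control_log_sd
        control_ratios = np.exp(rng.normal(mu, sd, cohort.n_control))
        susceptible = rng.random(cohort.n_defeated) < cohort.susceptible_fraction
        offsets = np.where(susceptible, spec.susceptible_offset, spec.resilient_offset)
        defeated_ratios = np.exp(rng.normal(mu + offsets, sd))
        for i, ratio in enumerate(control_ratios):
            records.append(_record(f"{strain}_C{i:04d}", strain, "control", ratio))
        for i, ratio in enumerate(defeated_ratios):
            records.append(_record(f"{strain}_D{i:04d}", strain, "defeated", ratio))
    return records


def _record(mouse_id: str, strain: str, group: str, ratio: float) -> BehavioralRecord:
    t_no = 30.0
    t_target = ratio / 100.0 * t_no
    if t_target > TRIAL_LENGTH_S:
        t_no = TRIAL_LENGTH_S * 100.0 / ratio
        t_target = TRIAL_LENGTH_S
    return BehavioralRecord(mouse_id, strain, group, t_no, t_target)


@dataclass
class SignalSpec:
    """Planted differential-expression signal for the omics simulators.

    ``planted_sets`` maps gene-set names to member feature identifiers;
    every member of a planted set receives the set's log2 ``effect_sizes``
    shift, multiplied by the strain's sign in ``strain_signs`` (opposite
    signs between strains reproduce the strain-divergent structure, but any
    signs are allowed), in samples of the groups named by
    ``affected_contrasts`` ("susceptible-vs-control" shifts susceptible
    samples relative to control, "resilient-vs-control" shifts resilient
    samples).
    """

    planted_sets: dict[str, list[str]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    strain_signs: dict[str, int] = field(default_factory=dict)
    affected_contrasts: tuple[str, ...] = ("susceptible-vs-control",)
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)
    batch_effect: float = 0.0  # SD of per-(feature, batch) log2 shifts
    # proteomics-only knobs
    ratio_noise_sd: float = 0.25  # biological SD of the log2 H/L ratio
    replicate_cv_range: tuple[float, float] = (0.02, 0.15)  # well-measured bulk
    noisy_protein_fraction: float = 0.2
    noisy_cv_range: tuple[float, float] = (0.35, 0.6)  # CV of the noisy minority
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise InvalidSpecError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("library_size_range must be positive and ordered")
        for s, sign in self.strain_signs.items():
            if sign not in (+1, -1):
                raise InvalidSpecError(f"strain sign for {s!r} must be +1 or -1")
        missing = set(self.planted_sets) - set(self.effect_sizes)
        if missing:
            raise InvalidSpecError(f"planted sets without an effect size: {sorted(missing)}")
        if self.ratio_noise_sd < 0:
            raise InvalidSpecError("ratio_noise_sd must be >= 0")
        for rng_field in (self.replicate_cv_range, self.noisy_cv_range):
            lo, hi = rng_field
            if lo < 0 or hi < lo:
                raise InvalidSpecError("CV ranges must be non-negative and ordered")
        if not (0.0 <= self.noisy_protein_fraction <= 1.0):
            raise InvalidSpecError("noisy_protein_fraction must be in [0, 1]")


def make_sample_meta(
    strains: Sequence[str],
    n_per_group: int,
    groups: Sequence[str] = ("control", "susceptible", "resilient"),
    tissue: str = "bnst",
    n_batches: int = 1,
    prefix: str = "s",
) -> pd.DataFrame:
    """Balanced sample metadata table: one row per sample, batches interleaved."""
    rows = []
    i = 0
    for strain in strains:
        for group in groups:
            for _ in range(n_per_group):
                rows.append(
                    {
                        "sample_id": f"{prefix}{i:04d}",
                        "strain": strain,
                        "tissue": tissue,
                        "group": group,
                        "batch": f"b{i % n_batches}",
                    }
                )
                i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _effect_shift(signal: SignalSpec, features: pd.Index, meta: pd.DataFrame) -> np.ndarray:
    """Per-(feature, sample) planted log2 shift matrix."""
    shift = np.zeros((len(features), len(meta)))
    fidx = {f: i for i, f in enumerate(features)}
    affected_groups = {c.split("-vs-")[0] for c in signal.affected_contrasts}
    col_on = np.array([g in affected_groups for g in meta["group"]])
    for set_name, members in signal.planted_sets.items():
        eff = signal.effect_sizes[set_name]
        rows = [fidx[m] for m in members]
        for j, (on, strain) in enumerate(zip(col_on, meta["strain"])):
            if on:
                sign = signal.strain_signs.get(strain, +1)
                shift[rows, j] += sign * eff
    return shift


def _check_members(signal: SignalSpec, features: pd.Index) -> None:
    known = set(features)
    for name, members in signal.planted_sets.items():
        unknown = set(members) - known
        if unknown:
            raise InvalidSpecError(
                f"planted set {name!r} has members outside the feature universe: "
                f"{sorted(unknown)[:5]}"
            )


def simulate_counts(
    n_features: int,
    samples: pd.DataFrame,
    signal: SignalSpec,
    feature_ids: Sequence[str] | None = None,
    modality: str = "mrna",
    base_mean_log: float = np.log(100.0),
    base_mean_sd: float = 1.0,
) -> OmicsMatrix:
    """Negative-binomial count matrix with planted strain-signed effects.

    Gene-wise baseline means are log-normal; the expected log2 difference of
    planted features between affected and control groups equals the planted
    effect with the strain-specific sign. Batch shifts are additive on the
    log2 scale and library-size factors rescale whole columns.
    """
    signal.validate()
    if feature_ids is None:
        feature_ids = [f"g{i:05d}" for i in range(n_features)]
    features = pd.Index(feature_ids)
    if len(features) != n_features:
        raise InvalidSpecError("feature_ids length must equal n_features")
    _check_members(signal, features)

    rng = _rng(signal.seed, _TAG_COUNTS)
    base = np.exp(rng.normal(base_mean_log, base_mean_sd, n_features))
    lo, hi = signal.library_size_range
    lib = rng.uniform(lo, hi, len(samples))

    log2_mu = np.log2(base)[:, None] + _effect_shift(signal, features, samples)
    if signal.batch_effect > 0:
        batches = samples["batch"].to_numpy()
        for b in pd.unique(batches):
            delta = rng.normal(0.0, signal.batch_effect, n_features)
            log2_mu[:, batches == b] += delta[:, None]
    mu = (2.0 ** log2_mu) * lib[None, :]

    size = 1.0 / signal.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    values = pd.DataFrame(counts, index=features, columns=samples.index)
    return OmicsMatrix(values, samples.copy(), modality)


@dataclass
class ProteomicsDataset:
    """Replicate-level H/L table plus the replicate-averaged log-ratio matrix.

    ``replicates`` columns: ``protein_id, sample_id, replicate,
    n_unique_peptides, hl_ratio`` (linear scale). ``matrix`` holds the log2
    mean H/L ratio over all replicates, before any inclusion filtering.
    """

    replicates: pd.DataFrame
    matrix: OmicsMatrix


def simulate_proteomics(
    n_proteins: int,
    samples: pd.DataFrame,
    signal: SignalSpec,
    protein_ids: Sequence[str] | None = None,
    n_replicates: int = 3,
    peptide_base_lambda: float = 2.0,
    peptide_dropout: float = 0.1,
) -> ProteomicsDataset:
    """Log-normal H/L ratio data with technical replicates and planted effects.

    Each sample is quantified against a pooled reference, so the expected
    log2 ratio is zero except for planted effects and biological noise.
    Replicate variability is a per-protein property: most proteins are
    well-measured (CV drawn from ``signal.replicate_cv_range``), while a
    ``noisy_protein_fraction`` minority gets CVs from ``noisy_cv_range``
    above the 30% inclusion cut. A protein's unique-peptide count is
    likewise stable across replicates (1 + Poisson(``peptide_base_lambda``))
    with occasional per-replicate dropout of one peptide, so the downstream
    inclusion filter (>= 2 unique peptides in >= 2 of 3 replicates,
    CV < 30%) has both passing and failing proteins to act on.
    """
    signal.validate()
    if n_replicates < 2:
        raise InvalidSpecError(f"need >= 2 technical replicates, got {n_replicates}")
    if protein_ids is None:
        protein_ids = [f"p{i:05d}" for i in range(n_proteins)]
    proteins = pd.Index(protein_ids)
    if len(proteins) != n_proteins:
        raise InvalidSpecError("protein_ids length must equal n_proteins")
    _check_members(signal, proteins)

    rng = _rng(signal.seed, _TAG_PROTEO)
    true_log2 = _effect_shift(signal, proteins, samples)
    if signal.ratio_noise_sd > 0:
        true_log2 = true_log2 + rng.normal(0.0, signal.ratio_noise_sd, true_log2.shape)

    noisy = rng.random(n_proteins) < signal.noisy_protein_fraction
    cv = np.where(
        noisy,
        rng.uniform(*signal.noisy_cv_range, n_proteins),
        rng.uniform(*signal.replicate_cv_range, n_proteins),
    )
    rep_sd = np.sqrt(np.log1p(cv**2))  # log-normal sigma giving that linear-scale CV
    base_peptides = 1 + rng.poisson(peptide_base_lambda, n_proteins)

    rows = []
    ratio_sum = np.zeros((n_proteins, len(samples)))
    for rep in range(n_replicates):
        noise = rng.normal(0.0, rep_sd[:, None], true_log2.shape)
        hl = (2.0 ** true_log2) * np.exp(noise)
        dropout = rng.random(true_log2.shape) < peptide_dropout
        n_pep = np.maximum(base_peptides[:, None] - dropout, 0)
        ratio_sum += hl
        for j, sample_id in enumerate(samples.index):
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": proteins,
                        "sample_id": sample_id,
                        "replicate": rep + 1,
                        "n_unique_peptides": n_pep[:, j],
                        "hl_ratio": hl[:, j],
                    }
                )
            )
    replicates = pd.concat(rows, ignore_index=True)
    mean_ratio = ratio_sum / n_replicates
    values = pd.DataFrame(np.log2(mean_ratio), index=proteins, columns=samples.index)
    matrix = OmicsMatrix(values, samples.copy(), "protein")
    return ProteomicsDataset(replicates, matrix)


def simulate_interactions(
    mirnas: Sequence[str],
    targets: Sequence[str],
    source_count_distribution: Sequence[float] = (0.3, 0.4, 0.3),
    seed: int = 0,
) -> pd.DataFrame:
    """All miRNA-target pairs with evidence-source counts drawn from {1, 2, 3}.

    ``source_count_distribution`` gives the probabilities of a pair being
    supported by 1, 2, or 3 evidence sources (prediction/validation tools).
    """
    probs = np.asarray(source_count_distribution, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise InvalidSpecError("source_count_distribution must be 3 probabilities summing to 1")
    if not mirnas or not targets:
        raise InvalidSpecError("mirnas and targets must be non-empty")
    rng = _rng(seed, _TAG_INTER)
    pairs = [(m, t) for m in mirnas for t in targets]
    n_sources = rng.choice([1, 2, 3], size=len(pairs), p=probs)
    return pd.DataFrame(
        {
            "mirna": [m for m, _ in pairs],
            "target": [t for _, t in pairs],
            "n_sources": n_sources,
        }
    )
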