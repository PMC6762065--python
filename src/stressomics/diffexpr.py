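"""Differential expression with an empirical-Bayes moderated t-statistic.

Count matrices are filtered on counts-per-million, transformed to log2-CPM
with a small pseudo-count, and optionally adjusted for batch by per-batch
mean-centering. Per feature, a group-means linear model gives the log2 fold
change and a residual variance s_g^2 with d_g degrees of freedom. The
residual variances are shrunk toward a common prior: assuming
s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_{d_g}/d_g and an inverse-chi-square
prior sigma_g^-2 ~ chi^2_{d0}/(d0 s0^2), the hyperparameters (d0, s0^2) are
estimated by matching the first two moments of log s_g^2 to a scaled log-F
distribution, and the posterior variance

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

replaces s_g^2 in the t-statistic, which then has d0 + d_g degrees of
freedom. This borrows strength across features and stabilizes inference at
the small group sizes typical of the designs analyzed here.

Multiple testing uses the Benjamini-Hochberg step-up adjustment. A feature
is called differentially expressed (DE) when its nominal P < 0.05 and its
linear fold change satisfies |FC| >= 1.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import InsufficientDataError, InvalidInputError, InvalidMatrixError
from .types import OmicsMatrix, de_table

__all__ = [
    "EBayesHyperparams",
    "cpm_filter",
    "log_cpm",
    "batch_center",
    "median_center",
    "estimate_hyperparams",
    "fit_moderated_t",
    "bh_adjust",
    "de_flag",
    "filter_proteins",
]


@dataclass
class EBayesHyperparams:
    """Estimated prior degrees of freedom d0 and prior variance s0^2."""

    d0: float  # may be math.inf when the variances show no excess spread
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


# ---------------------------------------------------------------------------
# normalization


def cpm_filter(matrix: OmicsMatrix, min_cpm: float = 1.0, min_samples: int = 6) -> OmicsMatrix:
    """Keep features with CPM >= min_cpm in at least min_samples samples.

    CPM_ij = 1e6 * count_ij / library_size_j with library size the column sum.
    The threshold is inclusive, so a feature sitting exactly at ``min_cpm``
    in enough samples is retained.
    """
    if not matrix.is_counts:
        raise InvalidMatrixError("cpm_filter applies to count modalities only")
    lib = matrix.values.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise InvalidMatrixError(f"zero library size for samples: {bad}")
    cpm = matrix.values * 1e6 / lib
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return OmicsMatrix(matrix.values.loc[keep], matrix.meta, matrix.modality)


def log_cpm(matrix: OmicsMatrix) -> OmicsMatrix:
    """log2 CPM with the +0.5 count / +1 library pseudo-count convention.

    value = log2( (count + 0.5) / (library + 1) * 1e6 ). Doubling all counts
    and library sizes leaves the result (essentially) unchanged.
    """
    if not matrix.is_counts:
        raise InvalidMatrixError("log_cpm applies to count modalities only")
    lib = matrix.values.sum(axis=0)
    vals = np.log2((matrix.values + 0.5) / (lib + 1.0) * 1e6)
    out = OmicsMatrix.__new__(OmicsMatrix)
    out.values, out.meta, out.modality = vals, matrix.meta, f"log-{matrix.modality}"
    return out


def batch_center(matrix: OmicsMatrix, batch: pd.Series | None = None) -> OmicsMatrix:
    """Remove per-batch location shifts, preserving each feature's grand mean.

    Per feature, each batch's mean is subtracted and the feature's grand
    mean (over all samples) added back. A single batch is the identity.
    This is a location-only batch adjustment, matching the additive batch
    effects the simulator plants; no scale adjustment is attempted.
    """
    if batch is None:
        batch = matrix.meta["batch"]
    batch = batch.reindex(matrix.values.columns)
    vals = matrix.values.copy()
    grand = vals.mean(axis=1)
    for b in pd.unique(batch):
        cols = batch.index[batch == b]
        vals[cols] = vals[cols].sub(vals[cols].mean(axis=1), axis=0).add(grand, axis=0)
    out = OmicsMatrix.__new__(OmicsMatrix)
    out.values, out.meta, out.modality = vals, matrix.meta, matrix.modality
    return out


def median_center(matrix: OmicsMatrix) -> OmicsMatrix:
    """Per-sample median-centering of log ratios (proteomics normalization)."""
    vals = matrix.values.sub(matrix.values.median(axis=0), axis=1)
    out = OmicsMatrix.__new__(OmicsMatrix)
    out.values, out.meta, out.modality = vals, matrix.meta, matrix.modality
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: np.ndarray | float, tol: float = 1e-8, max_iter: int = 100):
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing map).

    Uses the update on 1/x-like scale for stability; y must be positive.
    """
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # starting value: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < tol):
            break
    else:
        return None
    return x


def estimate_hyperparams(s_sq: np.ndarray, d_g: float) -> EBayesHyperparams:
    """Moment-match (d0, s0^2) from the spread of log residual variances.

    With z_g = log s_g^2, e_g = z_g - digamma(d_g/2) + log(d_g/2) has mean
    log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(d_g/2) + trigamma(d0/2). Excess spread of e_g beyond the
    sampling term trigamma(d_g/2) identifies trigamma(d0/2); no excess
    spread (or Newton non-convergence) falls back to d0 = inf, i.e. all
    features share the variance s0^2 = exp(mean e_g).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq[s_sq > 0]
    if positive.size == 0:
        raise InsufficientDataError("all residual variances are zero; cannot moderate")
    # guard log(0): features with zero residual variance are excluded from
    # hyperparameter estimation but still get shrunk posteriors afterwards
    e = np.log(positive) - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_bar = float(e.mean())
    n = e.size
    spread = float(((e - e_bar) ** 2).sum() / max(n - 1, 1))
    if spread == 0.0:
        # identical residual variances: nothing to shrink between, treat the
        # common variance as known at its observed value (no chi^2 correction,
        # which presumes sampling scatter that is manifestly absent)
        return EBayesHyperparams(np.inf, float(positive[0]))
    excess = spread - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0 or n < 2:
        return EBayesHyperparams(np.inf, float(np.exp(e_bar)))
    half_d0 = _trigamma_inverse(excess)
    if half_d0 is None:
        warnings.warn("trigamma inversion did not converge; falling back to d0 = inf")
        return EBayesHyperparams(np.inf, float(np.exp(e_bar)))
    d0 = 2.0 * float(half_d0)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesHyperparams(d0, s0_sq)


def fit_moderated_t(
    matrix: OmicsMatrix,
    contrast: str,
    group_col: str = "group",
    dataset: str = "dataset",
    hyperparams: EBayesHyperparams | None = None,
) -> tuple[pd.DataFrame, EBayesHyperparams]:
    """Moderated-t differential expression for one two-group contrast.

    ``contrast`` is "<groupA>-vs-<groupB>"; the log2 fold change is
    mean(groupA) - mean(groupB) per feature. Residual variance pools over
    all groups present in the matrix (group-means model). Returns the DE
    table (with BH-adjusted P) and the hyperparameters, which are estimated
    from the data unless pinned via ``hyperparams``.
    """
    try:
        g1, g2 = contrast.split("-vs-")
    except ValueError as exc:
        raise InvalidInputError(f"contrast must be '<a>-vs-<b>', got {contrast!r}") from exc
    groups = matrix.meta.loc[matrix.values.columns, group_col]
    for g in (g1, g2):
        n = int((groups == g).sum())
        if n < 2:
            raise InsufficientDataError(f"group {g!r} has {n} samples; need >= 2")

    vals = matrix.values.to_numpy(dtype=float)
    labels = groups.to_numpy()
    uniq = pd.unique(labels)
    n_samples, n_groups = vals.shape[1], len(uniq)
    d_g = n_samples - n_groups
    if d_g < 1:
        raise InsufficientDataError("no residual degrees of freedom in the group-means model")

    means = {g: vals[:, labels == g].mean(axis=1) for g in uniq}
    resid_ss = np.zeros(vals.shape[0])
    for g in uniq:
        resid_ss += ((vals[:, labels == g] - means[g][:, None]) ** 2).sum(axis=1)
    s_sq = resid_ss / d_g
    if np.all(s_sq == 0):
        raise InsufficientDataError("all residual variances are zero (degenerate matrix)")

    hp = hyperparams if hyperparams is not None else estimate_hyperparams(s_sq, d_g)
    if np.isinf(hp.d0):
        post_var = np.full_like(s_sq, hp.s0_sq)
        df_total = np.inf
    else:
        post_var = (hp.d0 * hp.s0_sq + d_g * s_sq) / (hp.d0 + d_g)
        df_total = hp.d0 + d_g

    n1, n2 = int((labels == g1).sum()), int((labels == g2).sum())
    logfc = means[g1] - means[g2]
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    padj = bh_adjust(p)
    return de_table(matrix.values.index, logfc, t, p, padj, contrast, dataset), hp


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    q_(i) = min_{j >= i} (m/j) p_(j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("pvalues must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def de_flag(
    result: pd.DataFrame, p_thresh: float = 0.05, fc_thresh: float = 1.2
) -> pd.DataFrame:
    """Flag DE features: nominal P < p_thresh (strict) and |FC| >= fc_thresh.

    Returns the flagged subset with a ``direction`` column (sign of logFC).
    """
    if fc_thresh < 1:
        raise InvalidInputError("fc_thresh is a linear fold change and must be >= 1")
    mask = (result["P"] < p_thresh) & (result["logFC"].abs() >= np.log2(fc_thresh))
    flagged = result.loc[mask].copy()
    flagged["direction"] = np.sign(flagged["logFC"]).astype(int)
    return flagged


# ---------------------------------------------------------------------------
# proteomics inclusion filter


def filter_proteins(
    replicates: pd.DataFrame,
    min_peptides: int = 2,
    min_replicates: int = 2,
    max_cv: float = 0.30,
) -> pd.DataFrame:
    """Apply the protein inclusion rule and average H/L over qualifying replicates.

    Per (protein, sample): retain when >= ``min_peptides`` unique peptides
    are observed in >= ``min_replicates`` of the replicates AND the
    coefficient of variation of the replicate H/L ratios is < ``max_cv``.
    The retained value is log2 of the mean H/L across the qualifying
    (peptide-sufficient) replicates.

    Input columns: ``protein_id, sample_id, replicate, n_unique_peptides,
    hl_ratio``. Returns ``protein_id, sample_id, log2_ratio, cv,
    n_qualifying``.
    """
    required = {"protein_id", "sample_id", "replicate", "n_unique_peptides", "hl_ratio"}
    missing = required - set(replicates.columns)
    if missing:
        raise InvalidInputError(f"replicate table missing columns: {sorted(missing)}")
    if replicates.empty:
        raise InvalidInputError("replicate table is empty")

    rows = []
    for (protein, sample), grp in replicates.groupby(["protein_id", "sample_id"], sort=True):
        if grp["replicate"].duplicated().any():
            raise InvalidInputError(
                f"duplicate replicate rows for protein {protein!r}, sample {sample!r}"
            )
        qualifying = grp.loc[grp["n_unique_peptides"] >= min_peptides]
        if len(qualifying) < min_replicates:
            continue
        ratios = grp["hl_ratio"].to_numpy(dtype=float)
        mean = ratios.mean()
        cv = float(ratios.std(ddof=1) / mean) if mean > 0 else np.inf
        if not (cv < max_cv):
            continue
        rows.append(
            {
                "protein_id": protein,
                "sample_id": sample,
                "log2_ratio": float(np.log2(qualifying["hl_ratio"].mean())),
                "cv": cv,
                "n_qualifying": int(len(qualifying)),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "sample_id", "log2_ratio", "cv", "n_qualifying"])
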