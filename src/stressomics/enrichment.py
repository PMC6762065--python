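"""Gene-set enrichment: preranked GSEA, hypergeometric ORA, activation z-score.

Preranked GSEA walks the ranked feature list accumulating a running sum that
rises by the (weighted) metric share at set members and falls by a constant
at non-members; the enrichment score (ES) is the signed maximum deviation
from zero. Significance comes from a permutation null built by drawing
random same-size member sets from the ranked universe (the only null
available for preranked input). The normalized score NES divides ES by the
mean |ES| of same-sign null draws, and the false-discovery rate uses the
standard pooled positive/negative null-NES procedure.

Overrepresentation analysis (ORA) is the classic upper-tail hypergeometric
test of a DE set against a gene set within a universe. The activation
z-score summarizes direction consistency between a signed regulon and DE
directions: z = (n_consistent - n_inconsistent) / sqrt(n_overlap).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedScoreError
from .diffexpr import bh_adjust
from .types import GeneSetCollection, SignedRegulon

__all__ = [
    "rank_metric",
    "gsea_es",
    "gsea_preranked",
    "hypergeom_ora",
    "ora_report",
    "activation_zscore",
]


def rank_metric(result: pd.DataFrame) -> pd.Series:
    """Ranking metric sign(logFC) x -log10(P), sorted descending.

    Ties are broken by |logFC| (larger first) and then feature identifier,
    so the ranked order is independent of input row order. Returns a Series
    indexed by feature id.
    """
    if result["feature_id"].duplicated().any():
        raise InvalidInputError("duplicate feature identifiers in DE result")
    p = result["P"].to_numpy(dtype=float)
    # P of exactly 0 would give an infinite metric; clip to a representable floor
    p = np.clip(p, np.finfo(float).tiny, None)
    metric = np.sign(result["logFC"].to_numpy()) * (-np.log10(p))
    df = pd.DataFrame(
        {
            "feature_id": result["feature_id"].to_numpy(),
            "metric": metric,
            "abs_lfc": result["logFC"].abs().to_numpy(),
        }
    )
    df = df.sort_values(
        ["metric", "abs_lfc", "feature_id"], ascending=[False, False, True], kind="mergesort"
    )
    return pd.Series(df["metric"].to_numpy(), index=df["feature_id"].to_numpy(), name="metric")


def gsea_es(
    ranked: pd.Series, members: Sequence[str], p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and running-sum profile for one gene set.

    The running sum increments by |metric|^p / sum_hits |metric|^p at member
    positions and decrements by 1/(N - N_hits) elsewhere; ES is the running
    sum value of largest absolute magnitude. Returns ``(es, running_sum)``
    where the profile has one entry per ranked feature.
    """
    hit = ranked.index.isin(set(members))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise UndefinedScoreError("gene set has no members in the ranked universe")
    n = len(ranked)
    if n_hits == n:
        raise InvalidInputError("gene set covers the whole universe; ES undefined")
    w = np.abs(ranked.to_numpy(dtype=float)) ** p
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all member metrics zero: fall back to unweighted hits
        w_hit = hit.astype(float)
        total = w_hit.sum()
    steps = w_hit / total - (~hit) / (n - n_hits)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _es_from_positions(positions: np.ndarray, absw: np.ndarray, n: int, p: float) -> np.ndarray:
    """Vectorized ES for many permutations given sorted hit positions.

    ``positions`` is (n_perm, k) of sorted 0-based ranks; ``absw`` is the
    |metric| vector of the ranked list. Only hit positions matter: between
    hits the running sum decays linearly, so its extrema occur either at a
    hit (upper candidates) or just before the next hit (lower candidates).
    """
    n_perm, k = positions.shape
    w = absw[positions] ** p
    tot = w.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    if zero.any():  # unweighted fallback per permutation
        w[zero] = 1.0
        tot[zero] = k
    cum_hits = np.cumsum(w, axis=1) / tot
    miss_step = 1.0 / (n - k)
    j = np.arange(k)
    # misses strictly before hit j: positions[:, j] - j
    before = cum_hits - w / tot - (positions - j) * miss_step  # value just before each hit
    at_hit = before + w / tot
    # also the tail after the last hit decays to 0, never beyond previous minima
    lo = before.min(axis=1)
    hi = at_hit.max(axis=1)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    comparison: str = "comparison",
) -> pd.DataFrame:
    """Preranked GSEA over a collection with a random-set permutation null.

    Returns one row per set: ``set_name, size, ES, NES, P, PFDR, method,
    comparison``. Sets with no member in the ranked universe are reported
    with NaN scores. The nominal P of a set is the fraction of same-sign
    null ES at least as extreme as the observed ES; the FDR q-value uses
    the pooled null-NES procedure (positive and negative sides separately).
    """
    if n_perm < 100:
        raise InvalidInputError(f"need n_perm >= 100, got {n_perm}")
    n = len(ranked)
    absw = np.abs(ranked.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    names, sizes, es_obs = [], [], []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in collection:
        in_univ = [m for m in members if m in ranked.index]
        k = len(in_univ)
        if k >= n:
            raise InvalidInputError(f"set {name!r} covers the whole ranked universe")
        names.append(name)
        sizes.append(k)
        if k == 0:
            es_obs.append(np.nan)
            continue
        es, _ = gsea_es(ranked, in_univ, p=weight)
        es_obs.append(es)
        if k not in null_by_size:
            # sample k positions without replacement per permutation
            r = rng.random((n_perm, n)).argpartition(k, axis=1)[:, :k]
            null_by_size[k] = _es_from_positions(np.sort(r, axis=1), absw, n, weight)

    es_obs = np.asarray(es_obs)
    nes = np.full(len(names), np.nan)
    pvals = np.full(len(names), np.nan)
    null_nes_pool: list[np.ndarray] = []
    for i, (k, es) in enumerate(zip(sizes, es_obs)):
        if k == 0 or not np.isfinite(es):
            continue
        null = null_by_size[k]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        null_scaled = np.where(null > 0, null / pos_mean, np.where(null < 0, null / neg_mean, 0.0))
        null_nes_pool.append(null_scaled[np.isfinite(null_scaled)])
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            warnings.warn(f"set {names[i]!r}: no same-sign null ES at n_perm={n_perm}")
            continue
        pvals[i] = float((np.abs(same_sign) >= abs(es)).mean())
        mean_abs = np.abs(same_sign).mean()
        nes[i] = es / mean_abs

    pfdr = _gsea_fdr(nes, np.concatenate(null_nes_pool) if null_nes_pool else np.array([]))
    # sets whose NES is undefined (empty same-sign null) report PFDR = 1
    pfdr = np.where(np.isfinite(nes), pfdr, np.where(np.asarray(sizes) > 0, 1.0, np.nan))
    return pd.DataFrame(
        {
            "set_name": names,
            "size": sizes,
            "ES": es_obs,
            "NES": nes,
            "P": pvals,
            "PFDR": pfdr,
            "method": "gsea",
            "comparison": comparison,
        }
    )


def _gsea_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Pooled positive/negative null-NES FDR of the preranked GSEA method."""
    q = np.full(nes.shape, np.nan)
    finite = np.isfinite(nes)
    if null_nes.size == 0 or not finite.any():
        return q
    obs = nes[finite]
    n_null_pos = max((null_nes >= 0).sum(), 1)
    n_null_neg = max((null_nes <= 0).sum(), 1)
    n_obs_pos = max((obs >= 0).sum(), 1)
    n_obs_neg = max((obs <= 0).sum(), 1)
    vals = np.empty(obs.shape)
    for i, x in enumerate(obs):
        if x >= 0:
            num = (null_nes >= x).sum() / n_null_pos
            den = (obs >= x).sum() / n_obs_pos
        else:
            num = (null_nes <= x).sum() / n_null_neg
            den = (obs <= x).sum() / n_obs_neg
        vals[i] = min(num / den, 1.0) if den > 0 else 1.0
    q[finite] = vals
    return q


def hypergeom_ora(
    de_set: Sequence[str], universe: Sequence[str], gene_set: Sequence[str]
) -> tuple[float, int, float]:
    """Upper-tail hypergeometric overrepresentation test.

    Returns ``(p, overlap, fold_enrichment)`` where fold enrichment is
    (k/|de|) / (|set in universe|/|universe|). The gene set is intersected
    with the universe before testing; the DE set must lie within the
    universe.
    """
    universe_s = set(universe)
    de_s = set(de_set)
    if not universe_s or not de_s:
        raise InvalidInputError("universe and de_set must be non-empty")
    outside = de_s - universe_s
    if outside:
        raise InvalidInputError(f"DE features outside the universe: {sorted(outside)[:5]}")
    set_in = set(gene_set) & universe_s
    k = len(de_s & set_in)
    M, K, n = len(universe_s), len(set_in), len(de_s)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    fold = (k / n) / (K / M) if K > 0 else np.nan
    return p, k, fold


def ora_report(results: pd.DataFrame, top_n: int = 100, fdr: float = 0.05) -> pd.DataFrame:
    """BH-adjust ORA P-values, keep PFDR < fdr, truncate to the top_n.

    ``results`` needs ``set_name`` and ``P`` columns; rows are ordered by
    (PFDR, P, set_name) before truncation. An empty report is a valid
    outcome, not an error.
    """
    if "P" not in results.columns or "set_name" not in results.columns:
        raise InvalidInputError("results must have 'set_name' and 'P' columns")
    out = results.copy()
    if out.empty:
        out["PFDR"] = pd.Series(dtype=float)
        return out
    out["PFDR"] = bh_adjust(out["P"].to_numpy())
    out = out.loc[out["PFDR"] < fdr]
    out = out.sort_values(["PFDR", "P", "set_name"], kind="mergesort")
    return out.head(top_n).reset_index(drop=True)


def activation_zscore(regulon: SignedRegulon, de_flagged: pd.DataFrame) -> tuple[float, int]:
    """Direction-consistency z-score of a signed regulon against DE directions.

    For each regulon target found in the flagged DE table, consistency is
    edge sign x DE direction (+1 when an activating edge meets up-regulation
    or a repressing edge meets down-regulation). z = sum(consistency) /
    sqrt(n_overlap); under random directions z is approximately standard
    normal. Returns ``(z, n_overlap)``.
    """
    directions = dict(zip(de_flagged["feature_id"], de_flagged["direction"]))
    consist = [
        sign * directions[t] for t, sign in regulon.targets.items() if t in directions
    ]
    if not consist:
        raise UndefinedScoreError(
            f"regulon {regulon.name!r} has no targets in the DE set"
        )
    n = len(consist)
    return float(sum(consist) / np.sqrt(n)), n
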