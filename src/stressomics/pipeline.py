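"""End-to-end synthetic-run orchestration.

``run_pipeline`` chains the stages simulate -> phenotype -> de -> gsea ->
integrate on a fully synthetic two-strain study, writing every intermediate
table and a machine-readable summary to the output directory. The simulated
design mirrors the analysis it exercises: two inbred strains (a largely
resilient and a largely susceptible one), three phenotype groups, an mRNA
and a protein layer sharing a gene-symbol universe, and one planted
"mitochondrial" gene set whose effect has opposite sign in the two strains.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import StressomicsError
from .types import CONTRASTS, GeneSetCollection
from .synthetic import (
    CohortSpec,
    SignalSpec,
    make_sample_meta,
    simulate_cohort,
    simulate_counts,
    simulate_interactions,
    simulate_proteomics,
)
from .phenotyping import phenotype_cohort, strain_phenotype_chi2, susceptibility_percentage
from .diffexpr import (
    batch_center,
    cpm_filter,
    de_flag,
    filter_proteins,
    fit_moderated_t,
    log_cpm,
    median_center,
)
from .enrichment import gsea_preranked, rank_metric
from .integration import (
    cross_strain_concordance,
    gsea_summary_filter,
    mirna_target_pairs,
    pathway_convergence,
)
from . import io as sio

__all__ = ["RunConfig", "run_pipeline", "PLANTED_SET"]

PLANTED_SET = "MITOCHONDRIAL_GENES"
ALL_STAGES = ("simulate", "phenotype", "de", "gsea", "integrate")


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run.

    Thresholds carry the analysis defaults: DE at nominal P < 0.05 with
    |FC| >= 1.2; pathway convergence at >= 2/12 comparisons with PFDR < 0.05
    and >= 4/12 with P < 0.05; miRNA-target pairs need > 2 evidence sources;
    the GSEA summary keeps sets at the exploratory 25% FDR in >= 50% of
    comparisons.
    """

    outdir: str = "stressomics_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation scale
    n_genes: int = 2000
    n_proteins: int = 600
    n_mirnas: int = 200
    n_per_group: int = 8
    planted_set_size: int = 50
    planted_effect: float = 1.0
    planted_mirnas: int = 8
    dispersion: float = 0.1
    batch_effect: float = 0.25
    n_batches: int = 2
    # thresholds
    p_thresh: float = 0.05
    fc_thresh: float = 1.2
    min_cpm: float = 1.0
    min_samples: int = 6
    min_sources: int = 3
    fdr_hits: int = 2
    nominal_hits: int = 4
    summary_fdr: float = 0.25
    summary_fraction: float = 0.5
    n_perm: int = 500
    n_random_sets: int = 20

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.p_thresh < 1) or self.fc_thresh < 1:
            raise ValueError("p_thresh must be in (0,1) and fc_thresh >= 1")


def _planted_collection(cfg: RunConfig, gene_ids: list[str], rng: np.random.Generator) -> tuple[GeneSetCollection, list[str]]:
    """Planted set drawn from the gene ids shared with the protein layer,
    plus random decoy sets of the same size."""
    shared = gene_ids[: cfg.n_proteins]
    members = sorted(rng.choice(shared, size=cfg.planted_set_size, replace=False).tolist())
    sets = {PLANTED_SET: members}
    categories = {PLANTED_SET: "mitochondria-related"}
    for i in range(cfg.n_random_sets):
        name = f"RANDOM_SET_{i:02d}"
        sets[name] = sorted(rng.choice(gene_ids, size=cfg.planted_set_size, replace=False).tolist())
        categories[name] = "mitochondria-unrelated"
    return GeneSetCollection(sets, categories=categories), members


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the summary bundle.

    Any stage error aborts with the failing stage named; tables written by
    earlier stages are retained. The summary (also written as
    ``summary.json``) is byte-identical across reruns with the same config.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir, state, summary)
        except StressomicsError as exc:
            raise StressomicsError(f"stage {stage!r} failed: {exc}") from exc
    _write_log(config, outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_log(config: RunConfig, outdir: Path) -> None:
    log = {
        "stressomics_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "p_thresh", "fc_thresh", "min_cpm", "min_samples", "min_sources",
                "fdr_hits", "nominal_hits", "summary_fdr", "summary_fraction", "n_perm",
            )
        },
        "stages": list(config.stages),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, outdir: Path, state: dict, summary: dict) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"mir{i:04d}" for i in range(cfg.n_mirnas)]
    collection, planted = _planted_collection(cfg, gene_ids, rng)
    planted_mirs = sorted(rng.choice(mirna_ids, size=cfg.planted_mirnas, replace=False).tolist())

    cohort_spec = CohortSpec(seed=cfg.seed)
    records = simulate_cohort(cohort_spec)
    sio.write_behavior(records, outdir / "behavior.tsv")
    state["records"] = records

    signal = SignalSpec(
        planted_sets={PLANTED_SET: planted},
        effect_sizes={PLANTED_SET: cfg.planted_effect},
        strain_signs={"B6": +1, "D2": -1},
        affected_contrasts=("susceptible-vs-control",),
        dispersion=cfg.dispersion,
        batch_effect=cfg.batch_effect,
        seed=cfg.seed,
    )
    # one combined two-strain matrix per layer: every sample gets its own
    # independent noise draw, and the strain sign flip lives in the signal
    state["matrices"] = {}
    meta = make_sample_meta(
        ["B6", "D2"], cfg.n_per_group, n_batches=cfg.n_batches, prefix="rna_"
    )
    rna = simulate_counts(cfg.n_genes, meta, signal, feature_ids=gene_ids)
    pmeta = make_sample_meta(["B6", "D2"], cfg.n_per_group, n_batches=1, prefix="prot_")
    prot_signal = SignalSpec(
        planted_sets={PLANTED_SET: planted},
        effect_sizes={PLANTED_SET: cfg.planted_effect},
        strain_signs={"B6": +1, "D2": -1},
        affected_contrasts=("susceptible-vs-control",),
        dispersion=cfg.dispersion,
        ratio_noise_sd=0.3,
        seed=cfg.seed,
    )
    prot = simulate_proteomics(
        cfg.n_proteins, pmeta, prot_signal, protein_ids=gene_ids[: cfg.n_proteins]
    )
    for strain in ("B6", "D2"):
        mat = rna.subset_samples(rna.meta.index[rna.meta["strain"] == strain])
        sio.write_matrix(mat, outdir / f"mrna_{strain}.tsv", outdir / f"mrna_{strain}.meta.tsv")
        state["matrices"][("mrna", strain)] = mat
        strain_samples = pmeta.index[pmeta["strain"] == strain]
        reps = prot.replicates.loc[prot.replicates["sample_id"].isin(strain_samples)]
        sio.write_table(reps, outdir / f"protein_replicates_{strain}.tsv")
        state[("proteomics", strain)] = type(prot)(
            reps.reset_index(drop=True), prot.matrix.subset_samples(strain_samples)
        )

    mir_signal = SignalSpec(
        planted_sets={"PLANTED_MIRNAS": planted_mirs},
        effect_sizes={"PLANTED_MIRNAS": cfg.planted_effect},
        strain_signs={"B6": +1},
        affected_contrasts=("susceptible-vs-control",),
        dispersion=cfg.dispersion,
        seed=cfg.seed + 7,
    )
    mmeta = make_sample_meta(["B6"], cfg.n_per_group, n_batches=1, prefix="B6_mir_")
    state["matrices"][("mirna", "B6")] = simulate_counts(
        cfg.n_mirnas, mmeta, mir_signal, feature_ids=mirna_ids, modality="mirna"
    )

    interactions = simulate_interactions(
        planted_mirs, planted, source_count_distribution=(0.3, 0.3, 0.4), seed=cfg.seed
    )
    sio.write_table(interactions, outdir / "interactions.tsv")
    state["interactions"] = interactions
    sio.write_gmt(collection, outdir / "gene_sets.gmt")
    state["collection"] = collection
    summary["simulate"] = {
        "n_genes": cfg.n_genes,
        "n_proteins": cfg.n_proteins,
        "planted_set": PLANTED_SET,
        "planted_set_size": len(planted),
        "n_interaction_pairs": int(len(interactions)),
    }


def _stage_phenotype(cfg: RunConfig, outdir: Path, state: dict, summary: dict) -> None:
    records = state.get("records")
    if records is None:
        records = sio.read_behavior(outdir / "behavior.tsv")
    calls = []
    pheno: dict = {}
    for strain in sorted({r.strain for r in records}):
        table = phenotype_cohort([r for r in records if r.strain == strain])
        calls.append(table)
        n_sus = int((table["label"] == "susceptible").sum())
        n_res = int((table["label"] == "resilient").sum())
        pheno[strain] = {
            "n_susceptible": n_sus,
            "n_resilient": n_res,
            "susceptibility_pct": susceptibility_percentage(n_sus, n_res),
            "border": float(table["border"].iloc[0]),
        }
    table = pd.concat(calls, ignore_index=True)
    sio.write_table(table, outdir / "phenotype_calls.tsv")
    if len(pheno) == 2:
        (s1, a), (s2, b) = sorted(pheno.items())
        chi2, p = strain_phenotype_chi2(
            [[a["n_susceptible"], a["n_resilient"]], [b["n_susceptible"], b["n_resilient"]]]
        )
        pheno["chi2"] = {"statistic": chi2, "P": p, "strains": [s1, s2]}
    summary["phenotype"] = pheno


def _stage_de(cfg: RunConfig, outdir: Path, state: dict, summary: dict) -> None:
    grid: dict[tuple[str, str, str], pd.DataFrame] = {}
    de_counts: dict[str, int] = {}
    for (modality, strain), mat in state["matrices"].items():
        filtered = cpm_filter(mat, cfg.min_cpm, min(cfg.min_samples, len(mat.samples) - 1))
        logged = batch_center(log_cpm(filtered))
        dataset = f"{modality}_{strain}"
        for contrast in CONTRASTS:
            de, _ = fit_moderated_t(logged, contrast, dataset=dataset)
            grid[(dataset, strain, contrast)] = de
            sio.write_table(de, outdir / f"de_{dataset}_{contrast}.tsv")
            de_counts[f"{dataset}/{contrast}"] = int(len(de_flag(de, cfg.p_thresh, cfg.fc_thresh)))
    for strain in ("B6", "D2"):
        prot = state.get(("proteomics", strain))
        if prot is None:
            continue
        retained = filter_proteins(prot.replicates)
        vals = retained.pivot(index="protein_id", columns="sample_id", values="log2_ratio")
        vals = vals.dropna(axis=0)  # keep proteins retained in every sample
        mat = prot.matrix
        pm = type(mat).__new__(type(mat))
        pm.values, pm.meta, pm.modality = vals, mat.meta, "protein"
        pm = median_center(pm)
        dataset = f"protein_{strain}"
        for contrast in CONTRASTS:
            de, _ = fit_moderated_t(pm, contrast, dataset=dataset)
            grid[(dataset, strain, contrast)] = de
            sio.write_table(de, outdir / f"de_{dataset}_{contrast}.tsv")
            de_counts[f"{dataset}/{contrast}"] = int(len(de_flag(de, cfg.p_thresh, cfg.fc_thresh)))
    state["grid"] = grid
    summary["de"] = {"n_flagged": de_counts}


def _stage_gsea(cfg: RunConfig, outdir: Path, state: dict, summary: dict) -> None:
    collection = state["collection"]
    enrich_grid: dict[tuple[str, str, str], pd.DataFrame] = {}
    planted_nes: dict[str, float] = {}
    for (dataset, strain, contrast), de in state["grid"].items():
        if dataset.startswith("mirna"):
            continue
        ranked = rank_metric(de)
        res = gsea_preranked(
            ranked,
            collection,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            comparison=f"{dataset}/{contrast}",
        )
        enrich_grid[(dataset, strain, contrast)] = res
        sio.write_table(res, outdir / f"gsea_{dataset}_{contrast}.tsv")
        row = res.loc[res["set_name"] == PLANTED_SET]
        if len(row):
            planted_nes[f"{dataset}/{contrast}"] = float(row["NES"].iloc[0])
    state["enrich_grid"] = enrich_grid
    summary["gsea"] = {"planted_set_nes": planted_nes, "n_comparisons": len(enrich_grid)}


def _stage_integrate(cfg: RunConfig, outdir: Path, state: dict, summary: dict) -> None:
    grid = state["grid"]
    out: dict = {}

    flag = lambda key: de_flag(grid[key], cfg.p_thresh, cfg.fc_thresh)
    conc = cross_strain_concordance(
        flag(("mrna_B6", "B6", "susceptible-vs-control")),
        flag(("mrna_D2", "D2", "susceptible-vs-control")),
    )
    out["concordance"] = {
        "n_common": len(conc.common),
        "n_same": conc.n_same,
        "n_opposite": conc.n_opposite,
        "opposite_fraction": conc.opposite_fraction,
        "P": conc.p_binomial,
    }

    enrich_grid = state["enrich_grid"]
    conv = pathway_convergence(
        enrich_grid, cfg.fdr_hits, cfg.nominal_hits, name_col="set_name"
    )
    sio.write_table(conv, outdir / "pathway_convergence.tsv")
    selected = conv.loc[conv["selected"], "set_name"].tolist()
    out["pathway_convergence"] = {
        "n_selected": len(selected),
        "selected": selected,
        "planted_set_selected": PLANTED_SET in selected,
    }

    summ, nes = gsea_summary_filter(enrich_grid, cfg.summary_fdr, cfg.summary_fraction)
    sio.write_table(nes.reset_index(), outdir / "gsea_summary_nes.tsv")
    out["gsea_summary"] = {
        "n_selected": int(summ["selected"].sum()),
        "planted_set_selected": bool(
            summ.loc[summ["set_name"] == PLANTED_SET, "selected"].any()
        ),
    }

    mir_key = ("mirna_B6", "B6", "susceptible-vs-control")
    if mir_key in grid and "interactions" in state:
        pairs = mirna_target_pairs(
            flag(mir_key),
            flag(("mrna_B6", "B6", "susceptible-vs-control")),
            state["interactions"],
            cfg.min_sources,
        )
        sio.write_table(pairs, outdir / "mirna_target_pairs.tsv")
        out["mirna_pairs"] = {"n_pairs": int(len(pairs))}

    summary["integrate"] = out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "phenotype": _stage_phenotype,
    "de": _stage_de,
    "gsea": _stage_gsea,
    "integrate": _stage_integrate,
}
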