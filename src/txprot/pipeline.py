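"""End-to-end orchestration: simulate -> preprocess -> diffexp ->
concordance -> enrichment (+ CETSA), writing per-stage artifacts and a
run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .concordance import (
    abundance_correlation,
    call_discordant,
    detection_overlap,
    fit_concordance,
    pair_fold_changes,
    run_pca,
)
from .core import (
    Contrast,
    ExpressionMatrix,
    SampleDesign,
    TIMEPOINTS,
    ValidationError,
    default_contrasts,
)
from .diffexpr import run_differential
from .enrichment import enrich, select_regulated, write_gmt
from .preprocess import (
    counts_to_tpm,
    filter_detected_proteins,
    filter_expressed_genes,
    impute_missing,
    median_normalize,
)
from .schild import analyze_cetsa
from .simdata import (
    SimConfig,
    simulate_cetsa,
    simulate_design,
    simulate_gene_sets,
    simulate_multiomics,
    CetsaParams,
)

DEFAULT_THRESHOLDS = {
    "min_tpm": 1.0,
    "min_samples": 3,
    "lower_fraction": 0.10,
    "lfc_threshold": 1.0,
    "residual_threshold": 3.0,
    "fdr_threshold": 0.25,
}

#: contrast whose fold changes enter the concordance fit
ANTAGONIST_CONTRAST = ("agonist_antagonist", "agonist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_inputs(cfg: SimConfig, outdir: Path, n_rep_rna: int = 5,
                    n_rep_protein: int = 3) -> dict:
    """Generate and write the full synthetic input bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = simulate_design(n_rep_rna, n_rep_protein)
    rna, protein, lengths, truth = simulate_multiomics(cfg, design)
    child = np.random.SeedSequence(cfg.seed).spawn(6)
    sets = simulate_gene_sets(
        truth, n_sets=10, set_size=min(50, cfg.n_genes),
        enrich_factor=10.0, seed=child[4],
    )
    cetsa = simulate_cetsa(
        agonist_doses=np.logspace(-9, np.log10(5e-6), 8),
        antagonist_concs=[0.0, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5],
        params=CetsaParams(ec50=2e-8, ki=1.2e-7),
        noise_sd=2.0,
        n_rep=4,
        seed=child[5],
    )
    io.write_design_tsv(design, outdir / "design.tsv")
    io.write_expression_tsv(rna, outdir / "rna_counts.tsv")
    io.write_expression_tsv(protein, outdir / "protein_log2_intensity.tsv")
    io.write_gene_lengths_tsv(lengths, outdir / "gene_lengths.tsv")
    truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "gene_sets.gmt", "w") as fh:
        write_gmt(sets, fh)
    io.write_cetsa_csv(cetsa, outdir / "cetsa.csv")
    return {
        "design": design, "rna": rna, "protein": protein,
        "lengths": lengths, "truth": truth, "gene_sets": sets,
        "cetsa": cetsa,
    }


def run_pipeline(
    rna: ExpressionMatrix,
    protein: ExpressionMatrix,
    lengths,
    design: SampleDesign,
    gene_sets: dict[str, list[str]],
    outdir: Path,
    thresholds: dict | None = None,
    seed: int = 0,
    cetsa=None,
    n_boot: int = 200,
) -> dict:
    """Run every analysis stage and write artifacts under ``outdir``.

    Returns an in-memory results dict mirroring what is written; a
    ``manifest.json`` records the seed, thresholds, input checksums and
    stage timings.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    # -- preprocess ------------------------------------------------------
    t0 = time.perf_counter()
    tpm = counts_to_tpm(rna, lengths)
    expressed = filter_expressed_genes(
        tpm, min_tpm=thr["min_tpm"], min_samples=thr["min_samples"]
    )
    tpm_f = tpm.subset_features(expressed)
    log_rna = ExpressionMatrix(
        np.log2(tpm_f.values + 0.5), layer="log2_tpm"
    )
    detected = filter_detected_proteins(protein, design)
    prot_f = protein.subset_features(detected)
    prot_norm = median_normalize(prot_f)
    prot_imp, imp_mask = impute_missing(
        prot_norm, lower_fraction=thr["lower_fraction"],
        rng=np.random.default_rng(seed),
    )
    timings["preprocess"] = time.perf_counter() - t0
    io.write_expression_tsv(log_rna, outdir / "rna_log2_tpm_filtered.tsv")
    io.write_expression_tsv(prot_imp, outdir / "protein_imputed.tsv")
    results.update(
        expressed_genes=expressed, detected_proteins=detected,
        log_rna=log_rna, protein_imputed=prot_imp,
    )

    # -- differential testing -------------------------------------------
    t0 = time.perf_counter()
    contrasts = default_contrasts()
    rna_diff = run_differential(log_rna, design, contrasts)
    prot_diff = run_differential(prot_imp, design, contrasts)
    timings["diffexp"] = time.perf_counter() - t0
    for name, tab in rna_diff.items():
        tab.to_csv(outdir / f"diff_rna_{name}.tsv", sep="\t",
                   index_label="feature_id")
    for name, tab in prot_diff.items():
        tab.to_csv(outdir / f"diff_protein_{name}.tsv", sep="\t",
                   index_label="feature_id")
    results.update(rna_diff=rna_diff, prot_diff=prot_diff)

    # -- concordance -----------------------------------------------------
    t0 = time.perf_counter()
    conc = {}
    for tp in TIMEPOINTS:
        cname = Contrast(*ANTAGONIST_CONTRAST, tp).name
        pairs = pair_fold_changes(rna_diff[cname], prot_diff[cname])
        fit = fit_concordance(pairs, threshold=thr["residual_threshold"])
        conc[tp] = fit
        fit.table.to_csv(outdir / f"concordance_{tp}.tsv", sep="\t",
                         index_label="feature_id")
    overlap = detection_overlap(expressed, detected)
    corr = abundance_correlation(
        log_rna.values.mean(axis=1), prot_imp.values.mean(axis=1)
    )
    pca_rna = run_pca(log_rna)
    pca_prot = run_pca(prot_imp)
    timings["concordance"] = time.perf_counter() - t0
    pca_rna.scores.to_csv(outdir / "pca_rna_scores.tsv", sep="\t",
                          index_label="sample_id")
    pca_prot.scores.to_csv(outdir / "pca_protein_scores.tsv", sep="\t",
                           index_label="sample_id")
    summary = {
        "abundance_correlation": corr,
        "overlap": {
            "n_rna_only": overlap.n_rna_only,
            "n_protein_only": overlap.n_protein_only,
            "n_both": overlap.n_both,
            "fraction_genes_with_protein":
                overlap.fraction_genes_with_protein,
        },
        "concordance": {tp: fit.summary() for tp, fit in conc.items()},
    }
    results.update(concordance=conc, overlap=overlap,
                   abundance_correlation=corr, pca_rna=pca_rna,
                   pca_prot=pca_prot)

    # -- enrichment ------------------------------------------------------
    t0 = time.perf_counter()
    enrich_tables = {}
    for tp, fit in conc.items():
        universe = list(fit.table.index)
        queries = {
            "discordant": call_discordant(fit, thr["residual_threshold"]),
            "up": [
                g for g in select_regulated(
                    results["prot_diff"][
                        Contrast(*ANTAGONIST_CONTRAST, tp).name
                    ],
                    thr["lfc_threshold"], "up",
                ) if g in set(universe)
            ],
            "down": [
                g for g in select_regulated(
                    results["prot_diff"][
                        Contrast(*ANTAGONIST_CONTRAST, tp).name
                    ],
                    thr["lfc_threshold"], "down",
                ) if g in set(universe)
            ],
        }
        for qname, query in queries.items():
            if not query:
                continue
            tab = enrich(query, universe, gene_sets,
                         fdr_threshold=thr["fdr_threshold"])
            enrich_tables[f"{qname}_{tp}"] = tab
            tab.to_csv(outdir / f"enrichment_{qname}_{tp}.tsv", sep="\t")
    timings["enrichment"] = time.perf_counter() - t0
    results["enrichment"] = enrich_tables

    # -- CETSA (optional) ------------------------------------------------
    if cetsa is not None:
        t0 = time.perf_counter()
        fits, schild = analyze_cetsa(cetsa, n_boot=n_boot, seed=seed)
        timings["cetsa"] = time.perf_counter() - t0
        report = schild.to_dict()
        report["curves"] = [
            {
                "antagonist_conc": f.antagonist_conc,
                "ec50_molar": f.ec50,
                "hill": f.hill,
                "top": f.top,
                "bottom": f.bottom,
                "rss": f.rss,
            }
            for f in fits
        ]
        (outdir / "cetsa_report.json").write_text(
            json.dumps(report, indent=2)
        )
        results["cetsa"] = (fits, schild)
        summary["ki_molar"] = schild.ki

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest = {
        "version": __version__,
        "seed": seed,
        "thresholds": thr,
        "timings_s": timings,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
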