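"""Synthetic paired multi-omics and isothermal dose-response data.

The generator emulates a three-condition (vehicle / agonist /
agonist+antagonist), two-timepoint cell-line experiment profiled at the
RNA level (negative-binomial counts) and at the protein level
(log2 label-free intensities with abundance-dependent non-detection).
Ground truth for every planted quantity is returned so that recovery
tests downstream are possible without external data.

Randomness model: one global seed is expanded into per-stage child
streams via ``numpy.random.SeedSequence.spawn``; the stage order is
fixed and documented in :func:`simulate_multiomics`, so identical
configuration + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    ASSAYS,
    CONDITIONS,
    TIMEPOINTS,
    ExpressionMatrix,
    GeneLengths,
    SampleDesign,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "CetsaParams",
    "CetsaDataset",
    "simulate_design",
    "simulate_multiomics",
    "simulate_gene_sets",
    "simulate_cetsa",
]


@dataclass
class SimConfig:
    """Parameters of the multi-omics generator.

    Effects are per-gene log2 fold changes ``beta_g`` drawn for induced
    (positive) and repressed (negative) genes; the antagonist reverses
    the agonist effect to ``beta_g * (1 - reversal_rho)``, the early
    timepoint scales effects by ``time_factor_early``, and protein log2
    shifts follow the RNA shift with per-gene coupling slope ``kappa_g``
    (``attenuation_lambda`` for concordant genes, ~Uniform(0, 0.1) for
    the planted discordant fraction).
    """

    n_genes: int = 5000
    frac_induced: float = 0.15
    frac_repressed: float = 0.10
    effect_mean: float = 2.0
    effect_sd: float = 0.8
    time_factor_early: float = 0.6
    reversal_rho: float = 0.9
    attenuation_lambda: float = 0.7
    frac_discordant: float = 0.015
    nb_dispersion_a0: float = 0.01
    nb_dispersion_a1: float = 2.0
    protein_noise_sd: float = 0.12
    detect_mid: float = 9.5
    detect_slope: float = 2.5
    rna_depth: float = 2e7
    # baseline abundance model (log2 scale)
    rna_baseline_mean: float = 4.0
    rna_baseline_sd: float = 1.5
    protein_baseline_mean: float = 16.0
    protein_baseline_sd: float = 2.0
    baseline_corr: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        for name in ("frac_induced", "frac_repressed", "frac_discordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.frac_induced + self.frac_repressed > 1.0:
            raise ValidationError("frac_induced + frac_repressed must be <= 1")
        if self.frac_discordant >= 1.0:
            raise ValidationError("frac_discordant must be < 1")
        if not 0.0 < self.time_factor_early <= 1.0:
            raise ValidationError("time_factor_early must lie in (0, 1]")
        if not 0.0 <= self.reversal_rho <= 1.0:
            raise ValidationError("reversal_rho must lie in [0, 1]")
        if not 0.0 < self.attenuation_lambda <= 1.0:
            raise ValidationError("attenuation_lambda must lie in (0, 1]")
        for name in ("effect_sd", "protein_noise_sd", "rna_baseline_sd",
                     "protein_baseline_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not -1.0 <= self.baseline_corr <= 1.0:
            raise ValidationError("baseline_corr must lie in [-1, 1]")
        if self.rna_depth <= 0:
            raise ValidationError("rna_depth must be positive")


@dataclass
class SimTruth:
    """Planted ground truth: one row per gene.

    Columns: ``gene_id``, ``gene_class`` (induced/repressed/null),
    ``beta`` (late-timepoint agonist-vs-vehicle log2FC), ``kappa``
    (protein coupling slope), ``discordant`` (bool), baseline log2
    abundances, and ``lfc_<contrast>_<timepoint>`` true RNA log2FCs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        disc = t["discordant"].to_numpy(dtype=bool)
        if (t.loc[disc, "kappa"] > 0.1 + 1e-12).any():
            raise ValidationError("discordant genes must have kappa <= 0.1")
        null = t["gene_class"] == "null"
        lfc_cols = [c for c in t.columns if c.startswith("lfc_")]
        if not np.allclose(t.loc[null, lfc_cols].to_numpy(dtype=float), 0.0):
            raise ValidationError("null genes must have all true log2FC = 0")

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.table.loc[self.table["gene_class"] == cls, "gene_id"])

    @property
    def discordant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["discordant"], "gene_id"])


@dataclass
class CetsaParams:
    """Generative four-parameter logistic + competitive-shift parameters."""

    ec50: float  # molar, control EC50
    ki: float  # molar
    top: float = 100.0
    bottom: float = 0.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.ki <= 0:
            raise ValidationError("ec50 and ki must be > 0")
        if self.hill <= 0:
            raise ValidationError("hill must be > 0")


@dataclass
class CetsaDataset:
    """Replicate-level isothermal dose-response measurements.

    ``table`` columns: agonist_dose (molar), antagonist_conc (molar,
    0 allowed for the control curve), replicate, signal.
    """

    table: pd.DataFrame
    true_params: CetsaParams | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = {"agonist_dose", "antagonist_conc", "replicate", "signal"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"CETSA table lacks columns {sorted(missing)}")
        if (t["agonist_dose"] <= 0).any():
            raise ValidationError("agonist doses must be > 0")
        if (t["antagonist_conc"] < 0).any():
            raise ValidationError("antagonist concentrations must be >= 0")
        for b, sub in t.groupby("antagonist_conc"):
            if sub["agonist_dose"].nunique() < 4:
                raise ValidationError(
                    f">= 4 distinct agonist doses required per antagonist "
                    f"concentration (got {sub['agonist_dose'].nunique()} at "
                    f"[B]={b:g})"
                )

    @property
    def antagonist_concs(self) -> np.ndarray:
        return np.sort(self.table["antagonist_conc"].unique())


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def simulate_design(n_rep_rna: int, n_rep_protein: int) -> SampleDesign:
    """Full-factorial design: 3 conditions x 2 timepoints x replicates.

    Returns one row per sample for each assay; sample ids encode the
    group, e.g. ``rna_agonist_early_r2``.
    """
    if n_rep_rna < 2 or n_rep_protein < 2:
        raise ValidationError("replicate counts must be >= 2")
    rows = []
    for assay, n_rep in (("rna", n_rep_rna), ("protein", n_rep_protein)):
        for cond in CONDITIONS:
            for tp in TIMEPOINTS:
                for r in range(1, n_rep + 1):
                    rows.append(
                        {
                            "sample_id": f"{assay}_{cond}_{tp}_r{r}",
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": r,
                            "assay": assay,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# multi-omics
# ---------------------------------------------------------------------------

def _condition_shift(beta: np.ndarray, cond: str, tp: str, cfg: SimConfig
                     ) -> np.ndarray:
    """True RNA log2 shift of a condition relative to vehicle."""
    tf = cfg.time_factor_early if tp == "early" else 1.0
    if cond == "vehicle":
        return np.zeros_like(beta)
    if cond == "agonist":
        return beta * tf
    if cond == "agonist_antagonist":
        return beta * (1.0 - cfg.reversal_rho) * tf
    raise ValidationError(f"unknown condition {cond!r}")


def simulate_multiomics(cfg: SimConfig, design: SampleDesign):
    """Generate paired RNA counts and protein log2 intensities.

    Stage seeds are spawned from ``SeedSequence(cfg.seed)`` in fixed
    order: 0 = per-gene parameters, 1 = RNA counts, 2 = protein noise,
    3 = protein detection.

    Returns ``(rna, protein, lengths, truth)`` where ``rna`` is a counts
    :class:`ExpressionMatrix`, ``protein`` a ``log2_intensity`` matrix
    with NaN for non-detected cells, ``lengths`` a :class:`GeneLengths`,
    and ``truth`` a :class:`SimTruth`.
    """
    assays = set(design.table["assay"])
    if set(ASSAYS) - assays:
        raise ValidationError("design must contain both rna and protein assays")

    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_rna, rng_prot, rng_detect = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n = cfg.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    # gene classes by index: induced block, repressed block, rest null
    n_ind = int(round(cfg.frac_induced * n))
    n_rep = int(round(cfg.frac_repressed * n))
    gene_class = np.array(["null"] * n, dtype=object)
    gene_class[:n_ind] = "induced"
    gene_class[n_ind:n_ind + n_rep] = "repressed"

    beta = np.zeros(n)
    if n_ind:
        beta[:n_ind] = np.abs(
            rng_genes.normal(cfg.effect_mean, cfg.effect_sd, n_ind)
        )
    if n_rep:
        beta[n_ind:n_ind + n_rep] = -np.abs(
            rng_genes.normal(cfg.effect_mean, cfg.effect_sd, n_rep)
        )

    # discordant genes: round(frac * n) of them, spread deterministically
    # across the gene index (even stride) so they cover regulated and
    # null classes in proportion; ties broken by gene index
    n_disc = int(round(cfg.frac_discordant * n))
    disc_idx = (
        np.floor(np.arange(n_disc) * n / n_disc).astype(int)
        if n_disc
        else np.array([], dtype=int)
    )
    discordant = np.zeros(n, dtype=bool)
    discordant[disc_idx] = True

    kappa = np.full(n, cfg.attenuation_lambda)
    kappa[disc_idx] = rng_genes.uniform(0.0, 0.1, n_disc)

    # correlated baselines through a shared latent factor
    z = rng_genes.normal(size=n)
    w = rng_genes.normal(size=n)
    r = cfg.baseline_corr
    rna_base = cfg.rna_baseline_mean + cfg.rna_baseline_sd * z
    prot_base = cfg.protein_baseline_mean + cfg.protein_baseline_sd * (
        r * z + math.sqrt(max(0.0, 1.0 - r * r)) * w
    )

    lengths = GeneLengths(
        pd.Series(
            rng_genes.integers(300, 10000, n).astype(float),
            index=gene_ids,
            name="length",
        )
    )

    # true RNA log2 shifts per (condition, timepoint)
    shifts = {
        (cond, tp): _condition_shift(beta, cond, tp, cfg)
        for cond in CONDITIONS
        for tp in TIMEPOINTS
    }

    # --- RNA counts: NB around depth-scaled baseline weights ------------
    # rna_base is the log2 concentration (TPM scale); expected reads are
    # proportional to concentration x transcript length, so that
    # log2 TPM tracks rna_base and the planted baseline correlation
    # survives length normalization
    base_weight = np.power(2.0, rna_base) * lengths.lengths.to_numpy() / 1000.0
    base_weight = base_weight / base_weight.sum()
    rna_samples = design.table[design.table["assay"] == "rna"]
    rna_cols = {}
    for row in rna_samples.itertuples(index=False):
        mu = cfg.rna_depth * base_weight * np.power(
            2.0, shifts[(row.condition, row.timepoint)]
        )
        phi = cfg.nb_dispersion_a0 + cfg.nb_dispersion_a1 / np.maximum(mu, 1e-8)
        size = 1.0 / phi
        p = size / (size + mu)
        rna_cols[row.sample_id] = rng_rna.negative_binomial(size, p)
    rna = ExpressionMatrix(
        pd.DataFrame(rna_cols, index=gene_ids), layer="counts"
    )

    # --- protein log2 intensities with MNAR detection -------------------
    prot_samples = design.table[design.table["assay"] == "protein"]
    prot_cols = {}
    for row in prot_samples.itertuples(index=False):
        x = (
            prot_base
            + kappa * shifts[(row.condition, row.timepoint)]
            + rng_prot.normal(0.0, cfg.protein_noise_sd, n)
        )
        p_detect = 1.0 / (1.0 + np.exp(-(x - cfg.detect_mid) * cfg.detect_slope))
        detected = rng_detect.random(n) < p_detect
        prot_cols[row.sample_id] = np.where(detected, x, np.nan)
    protein = ExpressionMatrix(
        pd.DataFrame(prot_cols, index=gene_ids), layer="log2_intensity"
    )

    truth_tab = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": gene_class,
            "beta": beta,
            "kappa": kappa,
            "discordant": discordant,
            "baseline_log2_rna": rna_base,
            "baseline_log2_protein": prot_base,
        }
    )
    for tp in TIMEPOINTS:
        truth_tab[f"lfc_agonist_vs_vehicle_{tp}"] = shifts[("agonist", tp)]
        truth_tab[f"lfc_agonist_antagonist_vs_vehicle_{tp}"] = shifts[
            ("agonist_antagonist", tp)
        ]
        truth_tab[f"lfc_agonist_antagonist_vs_agonist_{tp}"] = (
            shifts[("agonist_antagonist", tp)] - shifts[("agonist", tp)]
        )
    truth = SimTruth(truth_tab)
    return rna, protein, lengths, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

_ENRICHABLE_CLASSES = ("induced", "repressed", "discordant")


def simulate_gene_sets(
    truth: SimTruth,
    n_sets: int,
    set_size: int,
    enrich_factor: float = 1.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Draw gene sets enriched for planted gene classes.

    One set is biased toward each of induced / repressed / discordant
    genes (members sampled without replacement with weight
    ``enrich_factor`` vs 1); the remaining ``n_sets - 3`` sets are
    uniform draws.  With ``enrich_factor=1`` every set is uniform.
    """
    universe = truth.table["gene_id"].to_numpy()
    if set_size > len(universe):
        raise ValidationError("set_size exceeds the gene universe")
    if enrich_factor < 1.0:
        raise ValidationError("enrich_factor must be >= 1")
    if n_sets <= 0:
        raise ValidationError("n_sets must be positive")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for cls in _ENRICHABLE_CLASSES[: min(n_sets, 3)]:
        if cls == "discordant":
            in_cls = truth.table["discordant"].to_numpy(dtype=bool)
        else:
            in_cls = (truth.table["gene_class"] == cls).to_numpy()
        weights = np.where(in_cls, enrich_factor, 1.0)
        weights = weights / weights.sum()
        members = rng.choice(universe, size=set_size, replace=False, p=weights)
        sets[f"{cls}_biased"] = sorted(members.tolist())
    for i in range(max(0, n_sets - 3)):
        members = rng.choice(universe, size=set_size, replace=False)
        sets[f"random_{i + 1}"] = sorted(members.tolist())
    return sets


# ---------------------------------------------------------------------------
# CETSA dose-response
# ---------------------------------------------------------------------------

def gaddum_shifted_ec50(ec50: float, antagonist_conc: float, ki: float) -> float:
    """Competitive-antagonism EC50 shift: EC50_obs = EC50 * (1 + [B]/Ki)."""
    return ec50 * (1.0 + antagonist_conc / ki)


def four_pl(dose, ec50, top, bottom, hill):
    """Four-parameter logistic response at agonist dose (all molar)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def simulate_cetsa(
    agonist_doses,
    antagonist_concs,
    params: CetsaParams,
    noise_sd: float = 0.0,
    n_rep: int = 2,
    seed: int = 0,
) -> CetsaDataset:
    """Simulate replicate signals from the shifted 4PL model.

    For each antagonist concentration [B] the observed EC50 is the
    Gaddum-shifted ``ec50 * (1 + [B]/ki)``; Gaussian noise with
    ``noise_sd`` (signal units) is added independently per replicate.
    """
    agonist_doses = np.asarray(agonist_doses, dtype=float)
    antagonist_concs = np.asarray(antagonist_concs, dtype=float)
    if (agonist_doses <= 0).any():
        raise ValidationError("agonist doses must be > 0")
    if (antagonist_concs < 0).any():
        raise ValidationError("antagonist concentrations must be >= 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for b in antagonist_concs:
        ec50_obs = gaddum_shifted_ec50(params.ec50, b, params.ki)
        clean = four_pl(
            agonist_doses, ec50_obs, params.top, params.bottom, params.hill
        )
        for rep in range(1, n_rep + 1):
            noisy = clean + rng.normal(0.0, noise_sd, clean.shape) \
                if noise_sd > 0 else clean
            for dose, sig in zip(agonist_doses, noisy):
                rows.append(
                    {
                        "agonist_dose": dose,
                        "antagonist_conc": b,
                        "replicate": rep,
                        "signal": float(sig),
                    }
                )
    return CetsaDataset(pd.DataFrame(rows), true_params=params)
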