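"""Synthetic lymphoma cohorts with the structure the pipeline assumes.

Everything downstream (enrichment scoring, quadrant staging,
deconvolution, survival) can be exercised end-to-end on cohorts produced
here, with the generating truth retained for recovery checks:

* expression is log-normal: pure cell-type profiles have Gaussian log2
  baseline N(6, 1) with each type's signature genes raised by a log2
  effect; bulk samples are simplex mixtures (Dirichlet) of the pure
  profiles in linear space, re-logged;
* immune-escape quadrants are designed in: per sample a target IE stage
  is fixed, and the IEGS33 / T-cell-activation signature genes are
  shifted symmetrically — down by half the spike in designed-low stages,
  up by half in designed-high stages — so that with spikes of a few log2
  units the designed quadrants are recoverable against a random-gene-set
  threshold, while zero spikes collapse the design to exchangeability;
* survival is stage-dependent exponential, calibrated so that the
  expected 5-year survival per stage matches the published ordering
  70% (stage 2) > 48% (stage 3) > 44% (stage 1) > 38% (stage 4), with
  independent uniform censoring on [0, 120] months;
* immunohistochemistry marker percentages are stage-conditioned Beta
  draws (checkpoint-high in stages 3-4) — enough to exercise
  dichotomization and survival splits, not a biological claim.

A single seed drives everything through named child seeds
(SeedSequence.spawn order: profiles, fractions, stages, noise, survival,
markers), so identical seeds give bitwise-identical cohorts and each
stage could be re-drawn in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import FractionTable, SignatureMatrix
from .io import (
    ExpressionMatrix,
    GeneSet,
    IEGS33_STARTER,
    TCELL_ACTIVATION_STARTER,
    write_expression,
    write_gmt,
)

__all__ = ["GroupSpec", "CohortSpec", "SyntheticCohort",
           "simulate_cohort", "simulate_mixtures",
           "DEFAULT_CELL_TYPES", "FIVE_YEAR_SURVIVAL_BY_STAGE"]

#: Published 5-year overall survival by IE stage (stages 1..4).
FIVE_YEAR_SURVIVAL_BY_STAGE: tuple[float, float, float, float] = (
    0.44, 0.70, 0.48, 0.38,
)

DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "B_cells", "CD4_T_cells", "CD8_T_cells", "Tregs", "NK_cells",
    "monocytes", "M1_macrophages", "M2_macrophages", "dendritic_cells",
    "mast_cells", "neutrophils", "plasma_cells", "endothelial_cells",
    "fibroblasts",
)

CHECKPOINT_MARKERS = ("PD-1", "PD-L1", "LAG-3", "TIM-3")
TCELL_MARKERS = ("CD3", "CD4", "CD8")


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: its size and designed stage composition."""

    n: int
    stage_probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        p = np.asarray(self.stage_probs, dtype=float)
        if p.shape != (4,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("stage_probs must be 4 non-negative values summing to 1")


def _default_groups() -> dict[str, GroupSpec]:
    # Emulates the published cohort structure: nearly all cHL at stage 3;
    # non-GCB DLBCL with about a third at stage 3; GCB DLBCL mostly at
    # the immunologically quiet stages.
    return {
        "cHL": GroupSpec(100, (0.01, 0.01, 0.97, 0.01)),
        "non-GCB DLBCL": GroupSpec(200, (0.25, 0.23, 0.32, 0.20)),
        "GCB DLBCL": GroupSpec(100, (0.40, 0.35, 0.10, 0.15)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; the defaults are the conditions the pipeline
    is validated under."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    n_genes: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    genes_per_type: int = 30
    type_effect: float = 3.0  # log2 rise of a type's signature genes
    dirichlet_alpha: float = 1.0  # mixture simplex concentration (per group)
    iegs_spike: float = 3.0  # log2 quadrant placement, IEGS33 axis
    tact_spike: float = 3.0  # log2 quadrant placement, T-activation axis
    noise_sd: float = 0.5  # log2 measurement noise
    survival_s5: tuple[float, float, float, float] = FIVE_YEAR_SURVIVAL_BY_STAGE
    censoring: bool = True  # uniform on [0, 120] months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.genes_per_type < 1:
            raise ValueError("sizes must be >= 1")
        if min(self.iegs_spike, self.tact_spike, self.type_effect) < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(0 < s <= 1 for s in self.survival_s5):
            raise ValueError("survival targets must be in (0, 1]")
        if not self.groups:
            raise ValueError("need >= 1 group")

    @property
    def n_samples(self) -> int:
        return sum(g.n for g in self.groups.values())


@dataclass
class SyntheticCohort:
    """A generated cohort plus every generating truth."""

    expression: ExpressionMatrix
    fractions: FractionTable  # true mixing proportions
    stages: pd.DataFrame  # sample_id index; columns: group, stage
    survival: pd.DataFrame  # sample_id, time, event, group, stage
    markers: pd.DataFrame  # sample_id, marker, compartment, percent_positive
    signature: SignatureMatrix  # true pure-type profiles (linear scale)
    iegs_set: GeneSet
    tact_set: GeneSet
    spec: CohortSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the cohort in the formats every reader of the package
        accepts: GCT expression, GMT gene sets, TSV signature/fractions,
        CSV clinical/marker/stage-truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.gct",
            "gene_sets": outdir / "gene_sets.gmt",
            "signature": outdir / "signature.tsv",
            "fractions_true": outdir / "fractions_true.tsv",
            "clinical": outdir / "clinical.csv",
            "markers": outdir / "markers.csv",
            "stages_true": outdir / "stages_true.csv",
        }
        write_expression(self.expression, paths["expression"], fmt="gct")
        write_gmt([self.iegs_set, self.tact_set], paths["gene_sets"])
        self.signature.data.to_csv(paths["signature"], sep="\t", index_label="gene")
        self.fractions.data.to_csv(
            paths["fractions_true"], sep="\t", index_label="sample_id"
        )
        self.survival[["sample_id", "time", "event", "group"]].to_csv(
            paths["clinical"], index=False
        )
        self.markers.to_csv(paths["markers"], index=False)
        self.stages.to_csv(paths["stages_true"], index_label="sample_id")
        return paths


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _largest_remainder_counts(n: int, probs: np.ndarray) -> np.ndarray:
    """Deterministic integer allocation of n samples to the 4 stages."""
    raw = n * probs
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    return counts


def _expected_mixture_elevation(effect: float, n_types: int, alpha: float) -> float:
    """E[log2(1 + (2^effect - 1) f)] for f ~ Beta(alpha, (T-1) alpha),
    the Dirichlet marginal of the raised type's mixing fraction."""
    if effect == 0:
        return 0.0
    from scipy import integrate, stats

    c = 2.0**effect - 1.0
    pdf = stats.beta(alpha, (n_types - 1) * alpha).pdf
    val, _ = integrate.quad(lambda f: np.log2(1.0 + c * f) * pdf(f), 0.0, 1.0)
    return float(val)


def _synthetic_gene_universe(spec: CohortSpec) -> tuple[list[str], GeneSet, GeneSet, dict[str, list[str]]]:
    """Gene names: real starter symbols padded to the published set sizes
    (33 immune-escape, 44 T-activation; padding symbols are synthetic),
    disjoint per-type signature genes, and numbered filler."""
    iegs = list(IEGS33_STARTER) + [f"IEGS33_SYN{i}" for i in
                                   range(1, 34 - len(IEGS33_STARTER))]
    tact = list(TCELL_ACTIVATION_STARTER) + [f"TACT_SYN{i}" for i in
                                             range(1, 45 - len(TCELL_ACTIVATION_STARTER))]
    type_genes = {
        t: [f"SIG_{t}_{i}" for i in range(1, spec.genes_per_type + 1)]
        for t in spec.cell_types
    }
    named = iegs + tact + [g for gs in type_genes.values() for g in gs]
    if len(named) > spec.n_genes:
        raise ValueError(
            f"signature genes ({len(named)}) exceed n_genes ({spec.n_genes})"
        )
    filler = [f"GENE_{i:05d}" for i in range(1, spec.n_genes - len(named) + 1)]
    genes = named + filler
    return (
        genes,
        GeneSet("IEGS33", frozenset(iegs), "synthetic immune-escape set"),
        GeneSet("TCELL_ACTIVATION", frozenset(tact), "synthetic T-activation set"),
        type_genes,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def simulate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``spec`` (defaults above).

    Designed stages are allocated deterministically within each group by
    largest-remainder rounding of the group's stage proportions, then
    shuffled (seeded), so the designed stage composition is exact by
    construction.
    """
    spec = spec or CohortSpec()
    children = np.random.SeedSequence(spec.seed).spawn(6)
    rng_profiles = np.random.default_rng(children[0])
    rng_fracs = np.random.default_rng(children[1])
    rng_stages = np.random.default_rng(children[2])
    rng_noise = np.random.default_rng(children[3])
    rng_surv = np.random.default_rng(children[4])
    rng_marker = np.random.default_rng(children[5])

    genes, iegs_set, tact_set, type_genes = _synthetic_gene_universe(spec)
    G = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    T = len(spec.cell_types)

    # pure profiles: shared Gaussian baseline, type signature genes raised.
    # Marker rows are then lowered by the expected log2 elevation a mixture
    # inherits from the raised type (Jensen-corrected over the Dirichlet
    # marginal), so every gene's expected bulk level equals its baseline
    # and zero-spike cohorts stay exchangeable with random gene sets.
    baseline = rng_profiles.normal(6.0, 1.0, size=G)
    profiles_log2 = np.tile(baseline[:, None], (1, T))
    elev = _expected_mixture_elevation(spec.type_effect, T, spec.dirichlet_alpha)
    for j, t in enumerate(spec.cell_types):
        idx = [gene_pos[g] for g in type_genes[t]]
        profiles_log2[idx, j] += spec.type_effect
        profiles_log2[idx, :] -= elev
    profiles_lin = np.power(2.0, profiles_log2)

    # samples: group labels, designed stages, mixture fractions
    sample_ids: list[str] = []
    group_labels: list[str] = []
    designed: list[int] = []
    frac_rows: list[np.ndarray] = []
    counter = 0
    for gname, gspec in spec.groups.items():
        counts = _largest_remainder_counts(gspec.n, np.asarray(gspec.stage_probs))
        stages_g = np.repeat([1, 2, 3, 4], counts)
        rng_stages.shuffle(stages_g)
        alpha = np.full(T, spec.dirichlet_alpha)
        for s in stages_g:
            counter += 1
            sample_ids.append(f"S{counter:04d}")
            group_labels.append(gname)
            designed.append(int(s))
            frac_rows.append(rng_fracs.dirichlet(alpha))
    fracs = np.vstack(frac_rows)  # samples x types
    designed_arr = np.asarray(designed)

    # bulk expression: linear mixture, re-logged
    X = np.log2(profiles_lin @ fracs.T)  # genes x samples

    # symmetric quadrant placement: designed-high up by spike/2, others
    # down by spike/2 (net separation = spike; zero spike = exchangeable)
    iegs_idx = [gene_pos[g] for g in sorted(iegs_set.genes)]
    tact_idx = [gene_pos[g] for g in sorted(tact_set.genes)]
    iegs_high = np.isin(designed_arr, (3, 4))
    tact_high = np.isin(designed_arr, (2, 3))
    X[np.ix_(iegs_idx, np.arange(len(sample_ids)))] += np.where(
        iegs_high, spec.iegs_spike / 2.0, -spec.iegs_spike / 2.0
    )
    X[np.ix_(tact_idx, np.arange(len(sample_ids)))] += np.where(
        tact_high, spec.tact_spike / 2.0, -spec.tact_spike / 2.0
    )

    if spec.noise_sd > 0:
        X = X + rng_noise.normal(0.0, spec.noise_sd, size=X.shape)

    expression = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=sample_ids))
    fractions = FractionTable(
        pd.DataFrame(fracs, index=sample_ids, columns=list(spec.cell_types))
    )
    stages = pd.DataFrame(
        {"group": group_labels, "stage": designed_arr}, index=sample_ids
    )

    # stage-dependent exponential survival, monthly hazard -ln(S5)/60
    hazards = np.array([-np.log(s5) / 60.0 for s5 in spec.survival_s5])
    lam = hazards[designed_arr - 1]
    t_event = rng_surv.exponential(1.0 / lam)
    if spec.censoring:
        c = rng_surv.uniform(0.0, 120.0, size=len(lam))
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(len(lam), dtype=int)
    survival = pd.DataFrame(
        {"sample_id": sample_ids, "time": time, "event": event,
         "group": group_labels, "stage": designed_arr}
    )

    # stage-conditioned marker percentages (documented Beta shapes)
    marker_rows = []
    ckpt_high = np.isin(designed_arr, (3, 4))
    immunogenic = np.isin(designed_arr, (2, 3))
    for i, sid in enumerate(sample_ids):
        for m in CHECKPOINT_MARKERS:
            a_me, b_me = (3.0, 7.0) if ckpt_high[i] else (1.0, 19.0)
            a_tu, b_tu = (3.0, 6.0) if ckpt_high[i] else (1.0, 24.0)
            marker_rows.append(
                (sid, m, "ME", 100.0 * rng_marker.beta(a_me, b_me)))
            marker_rows.append(
                (sid, m, "tumor", 100.0 * rng_marker.beta(a_tu, b_tu)))
        for m in TCELL_MARKERS:
            a, b = (5.0, 4.0) if immunogenic[i] else (2.0, 8.0)
            marker_rows.append(
                (sid, m, "total", 100.0 * rng_marker.beta(a, b)))
    markers = pd.DataFrame(
        marker_rows,
        columns=["sample_id", "marker", "compartment", "percent_positive"],
    )

    signature = SignatureMatrix(
        pd.DataFrame(profiles_lin, index=genes, columns=list(spec.cell_types))
        .loc[[g for gs in type_genes.values() for g in gs]]
    )
    return SyntheticCohort(
        expression=expression, fractions=fractions, stages=stages,
        survival=survival, markers=markers, signature=signature,
        iegs_set=iegs_set, tact_set=tact_set, spec=spec,
    )


def simulate_mixtures(
    signature: SignatureMatrix, n: int, noise_sd: float = 0.0, seed: int = 0
) -> tuple[ExpressionMatrix, FractionTable]:
    """Bulk mixtures with known fractions, for deconvolution recovery.

    Fractions are flat Dirichlet(1, ..., 1); bulk = S f in linear space,
    then log2, then Gaussian noise of ``noise_sd`` log2 units.  Returns
    the log2 matrix plus the generating FractionTable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    S = signature.data.to_numpy()
    T = S.shape[1]
    fracs = rng.dirichlet(np.ones(T), size=n)  # n x T
    bulk = np.log2(S @ fracs.T)
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    sample_ids = [f"MIX{i:04d}" for i in range(1, n + 1)]
    matrix = ExpressionMatrix(
        pd.DataFrame(bulk, index=signature.genes, columns=sample_ids)
    )
    truth = FractionTable(
        pd.DataFrame(fracs, index=sample_ids, columns=signature.cell_types)
    )
    return matrix, truth
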