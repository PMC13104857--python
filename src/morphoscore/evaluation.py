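"""Evaluation procedures: leave-one-gene-out scoring with permutation
controls, rank-concordance analysis, and cross-plate replicate analysis.

Leave-one-gene-out (LOGO) guards against leakage when phenotype-labeled
cells are scored against a target population built from the same screen:
for each (phenotype, gene) pair, every cell of the held-out gene is removed
from the target population before signatures are derived, so a gene can
only score well by genuinely resembling the phenotype's morphology, not by
matching its own cells.  Two negative controls accompany it: permuting gene
labels to build a null for the concordance statistic, and shuffling feature
values column-wise (plus random signature reassignment) to destroy the
covariance structure while preserving label proportions.

The replicate analysis measures cross-plate score reproducibility: each
plate in turn serves as the reference plate, per-treatment signatures are
derived there (perturbed cells as reference state, subsampled control cells
as target state), and the same treatment — or, for the null condition, a
randomly permuted different treatment — is scored on every other plate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from .profiles import PopulationSelector, ProfileTable, SelectorLike, select_population
from .scoring import emd, off_score, on_score, reference_distance
from .signatures import SignatureResult, derive_signatures, shuffle_feature_assignment, shuffle_feature_values
from .stats import TestResult, bh_adjust, empirical_pvalue, kendalls_w, mann_whitney_u, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "LogoResult",
    "ConcordanceResult",
    "RankProportionResult",
    "ReplicateResult",
    "logo_analysis",
    "rank_concordance",
    "rank_vs_proportion",
    "replicate_analysis",
]


@dataclass
class LogoResult:
    """Per-(phenotype, gene) scores and ranks from a leave-one-gene-out run."""

    table: pd.DataFrame
    min_cells: int
    mode: str
    alpha: float
    # (phenotype, gene) -> (target row ids, query row ids); populated only
    # when the analysis runs with record_indices=True, for leakage audits
    indices: dict | None = None

    @property
    def scored(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]


@dataclass
class ConcordanceResult:
    """Kendall's W with its label-permutation null and the cross-phenotype
    Spearman matrix of gene-rank vectors."""

    observed_w: float
    null_w: np.ndarray
    empirical_p: float
    pairwise_spearman: pd.DataFrame
    genes: list[str]
    score: str


@dataclass
class RankProportionResult:
    """Pooled rank-vs-labeled-proportion correlation with per-phenotype tally."""

    rho: float
    p_value: float
    r_squared: float
    n_rows: int
    per_phenotype: pd.DataFrame
    n_negative: int
    n_phenotypes: int


@dataclass
class ReplicateResult:
    """Paired vs permuted cross-plate scores and their summary statistics."""

    scores: pd.DataFrame
    summary: pd.DataFrame
    n_iterations: int


def logo_analysis(
    profiles: ProfileTable,
    phenotype_col: str,
    gene_col: str,
    reference_selector: PopulationSelector | SelectorLike,
    alpha: float = 0.05,
    min_cells: int = 5,
    mode: str = "real",
    seed: int = 0,
    off_comparison: str = "target",
    query: str = "all_cells",
    phenotypes: list | None = None,
    record_indices: bool = False,
) -> LogoResult:
    """Leave-one-gene-out scoring of every (phenotype, gene) pair.

    For each phenotype, each gene contributing at least ``min_cells`` cells
    labeled with that phenotype is scored in turn: the target population is
    all cells of the phenotype excluding the held-out gene's cells, the
    reference population comes from ``reference_selector`` (the
    negative-control / interphase analog), signatures are derived between
    them, and the held-out gene's full perturbation group — all of its
    cells regardless of label (``query="all_cells"``), or only its
    phenotype-labeled cells (``query="phenotype_only"``) — receives an
    on-score and an off-score.  Genes with too few labeled cells or whose
    signature derivation leaves either signature empty are excluded with a
    recorded reason and carry no scores.

    ``mode="feature_shuffled"`` applies the covariance-destroying negative
    control: signatures are derived on the original profiles (so each keeps
    its real size), their on/off membership is randomly reassigned, and all
    scoring populations take their feature values from a column-wise
    permutation of the full table.  Deriving signatures on shuffled values
    directly would leave them empty — both populations then share the pooled
    marginal — which is why the control preserves the original sizes.
    """
    if mode not in ("real", "feature_shuffled"):
        raise ValueError("mode must be 'real' or 'feature_shuffled'")
    if query not in ("all_cells", "phenotype_only"):
        raise ValueError("query must be 'all_cells' or 'phenotype_only'")
    for col in (phenotype_col, gene_col):
        if col not in profiles.data.columns:
            raise KeyError(f"unknown column {col!r}")

    rng = np.random.default_rng(seed)
    df = profiles.data
    if mode == "feature_shuffled":
        shuffled_df = shuffle_feature_values(profiles, int(rng.integers(2**31))).data
    else:
        shuffled_df = df

    reference = select_population(profiles, reference_selector)
    if reference.n_cells == 0:
        raise ValueError("reference population is empty")
    ref_index = set(reference.data.index)
    reference_scored = ProfileTable(shuffled_df.loc[reference.data.index], validate=False)
    if phenotypes is None:
        ref_phenos = set(reference.data[phenotype_col].unique())
        phenotypes = sorted(set(df[phenotype_col].unique()) - ref_phenos)

    rows = []
    index_record: dict = {}
    for pheno in phenotypes:
        pheno_df = df[(df[phenotype_col] == pheno) & (~df.index.isin(ref_index))]
        gene_counts = pheno_df[gene_col].value_counts()
        for gene in sorted(gene_counts.index):
            n_labeled = int(gene_counts[gene])
            gene_all = df[(df[gene_col] == gene) & (~df.index.isin(ref_index))]
            proportion = n_labeled / len(gene_all)
            base = {
                "phenotype": pheno,
                "gene": gene,
                "n_heldout_cells": n_labeled,
                "labeled_cell_proportion": proportion,
            }
            if n_labeled < min_cells:
                rows.append({**base, "excluded": True, "exclusion_reason": "below min_cells"})
                continue
            target_df = pheno_df[pheno_df[gene_col] != gene]
            if len(target_df) < 2:
                rows.append({**base, "excluded": True, "exclusion_reason": "target too small"})
                continue
            target = ProfileTable(target_df, validate=False)
            sig = derive_signatures(reference, target, alpha=alpha)
            if mode == "feature_shuffled":
                sig = shuffle_feature_assignment(sig, int(rng.integers(2**31)))
            if not sig.on_features or not sig.off_features:
                rows.append({**base, "excluded": True, "exclusion_reason": "empty signature"})
                continue
            query_df = gene_all if query == "all_cells" else pheno_df[pheno_df[gene_col] == gene]
            # leakage guard: the held-out gene's cells must not be in the target
            leaked = set(query_df.index) & set(target_df.index)
            if leaked:
                raise AssertionError(f"LOGO leakage: {len(leaked)} held-out cells in target")
            if record_indices:
                index_record[(pheno, gene)] = (
                    frozenset(target_df.index),
                    frozenset(query_df.index),
                )
            # scoring populations: original values, or the column-shuffled
            # table in the negative-control mode
            target_scored = ProfileTable(shuffled_df.loc[target_df.index], validate=False)
            query_table = ProfileTable(shuffled_df.loc[query_df.index], validate=False)
            ref_dist = reference_distance(reference_scored, target_scored, sig)
            on = on_score(query_table, target_scored, sig, ref_dist)
            comparison = target_scored if off_comparison == "target" else reference_scored
            off, _ = off_score(query_table, comparison, sig)
            rows.append(
                {
                    **base,
                    "on_score": on,
                    "off_score": off,
                    "excluded": False,
                    "exclusion_reason": "",
                }
            )

    table = pd.DataFrame(rows)
    if len(table) and "on_score" not in table.columns:
        table["on_score"] = np.nan
        table["off_score"] = np.nan
    # ranks within each phenotype over the scored genes (midranks on ties)
    table["on_rank"] = np.nan
    table["off_rank"] = np.nan
    for pheno, idx in table[~table["excluded"]].groupby("phenotype").groups.items():
        table.loc[idx, "on_rank"] = rankdata(table.loc[idx, "on_score"])
        table.loc[idx, "off_rank"] = rankdata(table.loc[idx, "off_score"])
    return LogoResult(
        table=table,
        min_cells=min_cells,
        mode=mode,
        alpha=alpha,
        indices=index_record if record_indices else None,
    )


def rank_concordance(
    logo: LogoResult,
    score: str = "on",
    n_permutations: int = 5000,
    seed: int = 0,
    tie_correction: bool = True,
) -> ConcordanceResult:
    """Cross-phenotype concordance of gene rankings with a label-permutation null.

    Restricted to genes with complete rankings (scored in every phenotype).
    The observed Kendall's W is computed on the phenotype x gene rank
    matrix; the null redistributes gene labels within each phenotype
    independently per iteration; the empirical p-value is the proportion of
    permuted W values at least as large as the observed one.  The pairwise
    Spearman matrix of per-phenotype rank vectors is returned alongside.
    """
    if score not in ("on", "off"):
        raise ValueError("score must be 'on' or 'off'")
    scored = logo.scored
    wide = scored.pivot_table(index="phenotype", columns="gene", values=f"{score}_score")
    wide = wide.dropna(axis=1)  # complete rankings only
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 phenotypes")
    if wide.shape[1] < 2:
        raise ValueError("fewer than 2 genes with complete rankings")
    ranks = np.vstack([rankdata(row) for row in wide.to_numpy()])
    observed = kendalls_w(ranks, tie_correction=tie_correction)

    rng = np.random.default_rng(seed)
    m, n = ranks.shape
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted = np.vstack([row[rng.permutation(n)] for row in ranks])
        null[i] = kendalls_w(permuted, tie_correction=tie_correction)
    p = empirical_pvalue(observed, null, direction="ge")

    phenos = list(wide.index)
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if n >= 3:
                r = spearman_rho(ranks[i], ranks[j]).statistic
            else:
                r = np.nan
            mat[i, j] = mat[j, i] = r
    pairwise = pd.DataFrame(mat, index=phenos, columns=phenos)
    return ConcordanceResult(
        observed_w=observed,
        null_w=null,
        empirical_p=p,
        pairwise_spearman=pairwise,
        genes=list(wide.columns),
        score=score,
    )


def rank_vs_proportion(logo: LogoResult) -> RankProportionResult:
    """Correlation between on-score rank and labeled-cell proportion.

    Pools all scored (phenotype, gene) rows: Spearman correlation between a
    gene's within-phenotype on-rank and the proportion of its cells labeled
    with the phenotype, an R-squared from a least-squares fit of rank on
    proportion, and a per-phenotype tally of correlation signs (how many
    phenotypes individually show the negative association).
    """
    scored = logo.scored
    if len(scored) < 3:
        raise ValueError("need at least 3 scored (gene, phenotype) rows")
    ranks = scored["on_rank"].to_numpy(dtype=float)
    props = scored["labeled_cell_proportion"].to_numpy(dtype=float)
    overall = spearman_rho(props, ranks)
    fit = linregress(props, ranks)
    per_rows = []
    for pheno, grp in scored.groupby("phenotype"):
        if len(grp) < 3 or grp["labeled_cell_proportion"].nunique() < 2 or grp["on_rank"].nunique() < 2:
            per_rows.append({"phenotype": pheno, "rho": np.nan, "p_value": np.nan})
            continue
        r = spearman_rho(grp["labeled_cell_proportion"], grp["on_rank"])
        per_rows.append({"phenotype": pheno, "rho": r.statistic, "p_value": r.p_value})
    per = pd.DataFrame(per_rows)
    n_negative = int((per["rho"] < 0).sum())
    return RankProportionResult(
        rho=overall.statistic,
        p_value=overall.p_value,
        r_squared=float(fit.rvalue**2),
        n_rows=len(scored),
        per_phenotype=per,
        n_negative=n_negative,
        n_phenotypes=per["rho"].notna().sum(),
    )


def replicate_analysis(
    profiles: ProfileTable,
    plate_col: str,
    treatment_col: str,
    control_selector: PopulationSelector | SelectorLike,
    n_iterations: int = 10,
    control_subsample_fraction: float = 0.0002,
    alpha: float = 0.05,
    seed: int = 0,
    off_comparison: str = "target",
    subsample_floor: int = 50,
) -> ReplicateResult:
    """Cross-plate replicate consistency analysis.

    Each plate serves once as the reference plate.  For every treatment on
    it and every iteration: the plate's control cells are randomly
    subsampled by ``control_subsample_fraction`` (with a floor of
    ``subsample_floor`` cells — a warning is logged when the floor binds),
    signatures are derived with the treatment's reference-plate cells as
    the reference state and the subsampled controls as the target state,
    and the reference-plate distance normalizes all scores.  The same
    treatment on every other plate is then scored (condition ``paired``),
    as is a randomly drawn different treatment on that plate (condition
    ``non_paired``) — the null reflecting no replicate concordance.

    The summary compares paired vs non-paired distributions per score type
    with a two-sided Mann-Whitney U test, BH-corrected across score types.
    """
    for col in (plate_col, treatment_col):
        if col not in profiles.data.columns:
            raise KeyError(f"unknown column {col!r}")
    if not (0.0 < control_subsample_fraction <= 1.0):
        raise ValueError("control_subsample_fraction must lie in (0, 1]")
    df = profiles.data
    plates = sorted(df[plate_col].unique())
    if len(plates) < 2:
        raise ValueError("replicate analysis needs at least 2 plates")
    controls_all = select_population(profiles, control_selector)
    if controls_all.n_cells == 0:
        raise ValueError("control population is empty")
    control_treatments = set(controls_all.data[treatment_col].unique())
    treatments = sorted(set(df[treatment_col].unique()) - control_treatments)

    rng = np.random.default_rng(seed)
    rows = []
    floor_warned = False
    for ref_plate in plates:
        controls_ref = controls_all.data[controls_all.data[plate_col] == ref_plate]
        if len(controls_ref) < 2:
            logger.warning("no controls on plate %s; skipping as reference", ref_plate)
            continue
        for trt in treatments:
            trt_ref_df = df[(df[plate_col] == ref_plate) & (df[treatment_col] == trt)]
            if len(trt_ref_df) < 2:
                logger.warning("treatment %s absent from reference plate %s; skipped", trt, ref_plate)
                continue
            query_plates = [
                p
                for p in plates
                if p != ref_plate and ((df[plate_col] == p) & (df[treatment_col] == trt)).any()
            ]
            if not query_plates:
                logger.warning("treatment %s has no replicate on other plates; skipped", trt)
                continue
            trt_ref = ProfileTable(trt_ref_df, validate=False)
            for it in range(n_iterations):
                n_sub = max(subsample_floor, int(round(control_subsample_fraction * len(controls_ref))))
                if n_sub >= len(controls_ref):
                    if not floor_warned:
                        logger.warning(
                            "control subsample floor (%d) meets or exceeds the control pool "
                            "(%d cells); using all controls",
                            subsample_floor,
                            len(controls_ref),
                        )
                        floor_warned = True
                    sub_controls = ProfileTable(controls_ref, validate=False)
                elif n_sub == subsample_floor and not floor_warned:
                    logger.warning(
                        "control subsample floor of %d cells binds (fraction %.2g of %d = %.1f)",
                        subsample_floor,
                        control_subsample_fraction,
                        len(controls_ref),
                        control_subsample_fraction * len(controls_ref),
                    )
                    floor_warned = True
                if n_sub < len(controls_ref):
                    idx = rng.choice(len(controls_ref), size=n_sub, replace=False)
                    sub_controls = ProfileTable(controls_ref.iloc[np.sort(idx)], validate=False)
                sig = derive_signatures(trt_ref, sub_controls, alpha=alpha)
                if not sig.on_features or not sig.off_features:
                    logger.warning(
                        "empty signature for treatment %s on reference plate %s (iteration %d); skipped",
                        trt,
                        ref_plate,
                        it,
                    )
                    continue
                ref_dist = reference_distance(trt_ref, sub_controls, sig)
                comparison = sub_controls if off_comparison == "target" else trt_ref
                target_on = sub_controls.values(sig.on_features)
                for q_plate in query_plates:
                    q_df = df[df[plate_col] == q_plate]
                    other_trts = sorted(set(q_df[treatment_col].unique()) - control_treatments - {trt})
                    pairings = [("paired", trt)]
                    if other_trts:
                        pairings.append(("non_paired", other_trts[rng.integers(len(other_trts))]))
                    for condition, q_trt in pairings:
                        q_cells_df = q_df[q_df[treatment_col] == q_trt]
                        if len(q_cells_df) < 2:
                            continue
                        q_cells = ProfileTable(q_cells_df, validate=False)
                        raw = emd(q_cells.values(sig.on_features), target_on)
                        off, _ = off_score(q_cells, comparison, sig)
                        rows.append(
                            {
                                "reference_plate": ref_plate,
                                "query_plate": q_plate,
                                "treatment": trt,
                                "scored_treatment": q_trt,
                                "condition": condition,
                                "iteration": it,
                                "on_score": raw / ref_dist,
                                "off_score": off,
                            }
                        )
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise ValueError("no cross-plate comparisons could be scored")

    summary_rows = []
    pvals = []
    for score_type in ("on_score", "off_score"):
        paired = scores.loc[scores["condition"] == "paired", score_type].to_numpy()
        non_paired = scores.loc[scores["condition"] == "non_paired", score_type].to_numpy()
        res = mann_whitney_u(paired, non_paired)
        pvals.append(res.p_value)
        summary_rows.append(
            {
                "score_type": score_type.replace("_score", ""),
                "mean_paired": paired.mean(),
                "sd_paired": paired.std(ddof=1),
                "mean_non_paired": non_paired.mean(),
                "sd_non_paired": non_paired.std(ddof=1),
                "u_statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    adjusted, _ = bh_adjust(pvals, alpha=alpha)
    summary = pd.DataFrame(summary_rows)
    summary["p_adjusted"] = adjusted
    return ReplicateResult(scores=scores, summary=summary, n_iterations=n_iterations)
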