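"""Fitness estimation from high-throughput sequencing read counts.

Two assays, two estimators:

* **Self-cleavage (HDV).**  During co-transcriptional cleavage each read
  is observed either cleaved or uncleaved.  A genotype's activity per
  replicate is its fraction cleaved, ``cleaved / (cleaved + uncleaved)``,
  normalized by the fraction cleaved of a designated reference genotype
  so the reference scores exactly 1.

* **Ligation selection (Ligase).**  Fitness is the enrichment of a
  genotype across one round of selection: relative abundance after
  selection divided by relative abundance before, again normalized to a
  reference genotype's enrichment.

Fitness per genotype is the mean of the per-replicate values and *delta*
is the standard error of that mean across replicates.  A genotype counts
as **active** only if it is detected at least once in every replicate
and at least three times in total; inactive genotypes are assigned
fitness 0 so that downstream landscape analyses are total functions on
the genotype space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_space import Genotype

__all__ = [
    "RateConstants",
    "fraction_cleaved",
    "detection_filter",
    "hdv_fitness",
    "ligase_fitness",
    "ligation_rate_estimate",
    "frequency_fitness_correlation",
    "validate_read_counts",
]

#: literature rate constants for the uncatalyzed background reactions (min^-1)
UNCATALYZED_CLEAVAGE_RATE = 7e-7
NONENZYMATIC_LIGATION_2P5 = 2.4e-10
NONENZYMATIC_LIGATION_3P5 = 1.5e-8


@dataclass(frozen=True)
class RateConstants:
    """Rate constants (min^-1) used to map relative fitness to catalytic rates.

    ``anchor_fitness``/``anchor_rate`` calibrate the linear fitness-to-rate
    map: a genotype of the anchor fitness is assigned the anchor rate.
    """

    anchor_fitness: float
    anchor_rate: float
    uncatalyzed_cleavage_rate: float = UNCATALYZED_CLEAVAGE_RATE
    nonenzymatic_ligation_2p5: float = NONENZYMATIC_LIGATION_2P5
    nonenzymatic_ligation_3p5: float = NONENZYMATIC_LIGATION_3P5

    def __post_init__(self) -> None:
        for name in (
            "anchor_fitness",
            "anchor_rate",
            "uncatalyzed_cleavage_rate",
            "nonenzymatic_ligation_2p5",
            "nonenzymatic_ligation_3p5",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def validate_read_counts(table: pd.DataFrame, count_cols: tuple[str, str]) -> pd.DataFrame:
    """Validate a long-format read-count table.

    Required columns: ``genotype``, ``replicate`` and the two assay count
    columns (``cleaved``/``uncleaved`` or ``pre``/``post``).  Counts must
    be non-negative integers and (genotype, replicate) pairs unique.
    """
    required = {"genotype", "replicate", *count_cols}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"read-count table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["genotype", "replicate"])
    if dup.any():
        g, r = table.loc[dup.idxmax(), ["genotype", "replicate"]]
        raise ValueError(f"duplicate (genotype, replicate) entry: ({g!r}, {r!r})")
    for col in count_cols:
        vals = table[col].to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError(f"column {col!r} must hold non-negative integers")
    return table


def fraction_cleaved(cleaved: float, uncleaved: float) -> float:
    """Fraction of a genotype's reads observed in the cleaved form."""
    total = cleaved + uncleaved
    if total <= 0:
        raise ValueError("fraction cleaved undefined: zero total reads")
    return cleaved / total


def detection_filter(active_counts_per_replicate) -> bool:
    """Activity-detection threshold.

    A genotype is called active only when it is detected at least once in
    *every* replicate and at least three times overall (with the standard
    three replicates the per-replicate condition implies the total).
    """
    counts = list(active_counts_per_replicate)
    if not counts:
        return False
    return all(c >= 1 for c in counts) and sum(counts) >= 3


def _summarize_replicates(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of per-replicate fitness values.

    *per_rep* is indexed by genotype with one column per replicate; NaN
    marks a replicate where the value is undefined for that genotype.
    """
    mean = per_rep.mean(axis=1, skipna=True)
    n = per_rep.notna().sum(axis=1)
    sd = per_rep.std(axis=1, ddof=1, skipna=True)
    sem = (sd / np.sqrt(n)).where(n > 1, 0.0).fillna(0.0)
    return pd.DataFrame({"fitness": mean, "delta": sem})


def hdv_fitness(table: pd.DataFrame, normalizer: Genotype) -> pd.DataFrame:
    """Relative self-cleavage fitness from cleaved/uncleaved counts.

    Per replicate, fitness is the genotype's fraction cleaved divided by
    the *normalizer* genotype's fraction cleaved; per-genotype fitness is
    the mean across replicates and delta its standard error.  Genotypes
    failing the detection filter (cleaved counts) are set to fitness 0.

    Returns a DataFrame with columns genotype, fitness, delta, active;
    QC tallies are stored in ``result.attrs["qc"]``.
    """
    validate_read_counts(table, ("cleaved", "uncleaved"))
    wide_c = table.pivot(index="genotype", columns="replicate", values="cleaved")
    wide_u = table.pivot(index="genotype", columns="replicate", values="uncleaved")
    if normalizer not in wide_c.index:
        raise ValueError(f"normalizer genotype {normalizer!r} not in table")
    total = wide_c + wide_u
    frac = wide_c / total.where(total > 0)
    norm_frac = frac.loc[normalizer]
    if norm_frac.isna().any() or (norm_frac <= 0).any():
        bad = norm_frac.index[(norm_frac.isna()) | (norm_frac <= 0)].tolist()
        raise ValueError(
            f"normalizer has zero cleavage or zero total reads in replicates {bad}"
        )
    per_rep = frac.div(norm_frac, axis=1)
    out = _summarize_replicates(per_rep)

    active = wide_c.fillna(0).apply(lambda row: detection_filter(row.to_numpy()), axis=1)
    n_zero_total = int((total.fillna(0) == 0).any(axis=1).sum())
    out["active"] = active
    out.loc[~active, ["fitness", "delta"]] = 0.0
    out = out.reset_index()[["genotype", "fitness", "delta", "active"]]
    out.attrs["qc"] = {
        "n_genotypes": len(out),
        "n_inactive": int((~active).sum()),
        "n_zero_total_some_replicate": n_zero_total,
        "normalizer": normalizer,
    }
    return out


def ligase_fitness(table: pd.DataFrame, normalizer: Genotype) -> pd.DataFrame:
    """Relative ligation fitness from pre-/post-selection counts.

    Per replicate, enrichment is the genotype's post-selection relative
    abundance divided by its pre-selection relative abundance, normalized
    by the same ratio for *normalizer*.  A genotype absent post-selection
    in a replicate contributes enrichment 0 there; one absent
    pre-selection in a replicate has no defined value in that replicate.
    Genotypes absent pre-selection in every replicate are flagged in the
    QC tally and returned as inactive with fitness 0.
    """
    validate_read_counts(table, ("pre", "post"))
    wide_pre = table.pivot(index="genotype", columns="replicate", values="pre")
    wide_post = table.pivot(index="genotype", columns="replicate", values="post")
    if normalizer not in wide_pre.index:
        raise ValueError(f"normalizer genotype {normalizer!r} not in table")
    rel_pre = wide_pre / wide_pre.sum(axis=0)
    rel_post = wide_post / wide_post.sum(axis=0)
    enr = (rel_post / rel_pre.where(rel_pre > 0))
    # absent post-selection => enrichment 0 in that replicate (pre present)
    enr = enr.where(~((rel_pre > 0) & (rel_post == 0)), 0.0)
    norm_enr = enr.loc[normalizer]
    if norm_enr.isna().any() or (norm_enr <= 0).any():
        bad = norm_enr.index[(norm_enr.isna()) | (norm_enr <= 0)].tolist()
        raise ValueError(
            f"normalizer has undefined or zero enrichment in replicates {bad}"
        )
    per_rep = enr.div(norm_enr, axis=1)
    out = _summarize_replicates(per_rep)

    never_pre = (wide_pre.fillna(0) == 0).all(axis=1)
    active = wide_post.fillna(0).apply(lambda row: detection_filter(row.to_numpy()), axis=1)
    active &= ~never_pre
    out["active"] = active
    out.loc[~active, ["fitness", "delta"]] = 0.0
    out.loc[never_pre, ["fitness", "delta"]] = 0.0
    out = out.reset_index()[["genotype", "fitness", "delta", "active"]]
    out.attrs["qc"] = {
        "n_genotypes": len(out),
        "n_inactive": int((~active).sum()),
        "n_absent_preselection": int(never_pre.sum()),
        "normalizer": normalizer,
    }
    return out


def ligase_fitness_pooled_normalization(table: pd.DataFrame, normalizer: Genotype) -> pd.DataFrame:
    """Sensitivity variant: average enrichment across replicates first,
    then normalize by the normalizer's averaged enrichment."""
    validate_read_counts(table, ("pre", "post"))
    wide_pre = table.pivot(index="genotype", columns="replicate", values="pre")
    wide_post = table.pivot(index="genotype", columns="replicate", values="post")
    rel_pre = wide_pre / wide_pre.sum(axis=0)
    rel_post = wide_post / wide_post.sum(axis=0)
    enr = (rel_post / rel_pre.where(rel_pre > 0)).where(
        ~((rel_pre > 0) & (rel_post == 0)), 0.0
    )
    mean_enr = enr.mean(axis=1, skipna=True)
    norm = mean_enr.loc[normalizer]
    if not norm > 0:
        raise ValueError("normalizer mean enrichment is zero or undefined")
    out = pd.DataFrame(
        {"genotype": mean_enr.index, "fitness": (mean_enr / norm).to_numpy()}
    )
    return out.reset_index(drop=True)


def ligation_rate_estimate(fitness: float, constants: RateConstants) -> float:
    """Estimated ligation rate (min^-1): linear-through-origin calibration.

    rate = fitness * anchor_rate / anchor_fitness.
    """
    return fitness * constants.anchor_rate / constants.anchor_fitness


def frequency_fitness_correlation(
    pre_table: pd.DataFrame, fitness: pd.DataFrame
) -> dict[str, float]:
    """Correlation between pre-selection frequency and estimated fitness.

    Used as a QC check that selection-based fitness estimates are not an
    artifact of genotype abundance in the input library.  Returns Pearson
    and Spearman coefficients with p-values.
    """
    validate_read_counts(pre_table, ("pre", "post"))
    wide_pre = pre_table.pivot(index="genotype", columns="replicate", values="pre")
    freq = (wide_pre / wide_pre.sum(axis=0)).mean(axis=1)
    merged = pd.DataFrame({"freq": freq}).join(
        fitness.set_index("genotype")["fitness"], how="inner"
    ).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 matched genotypes for correlation")
    if merged["fitness"].nunique() == 1 or merged["freq"].nunique() == 1:
        warnings.warn("zero variance in fitness or frequency; correlation undefined")
        return {"pearson_r": 0.0, "pearson_p": 1.0, "spearman_r": 0.0, "spearman_p": 1.0}
    pr = stats.pearsonr(merged["freq"], merged["fitness"])
    sr = stats.spearmanr(merged["freq"], merged["fitness"])
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }
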