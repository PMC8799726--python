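"""Normalisation and quantification: pool/control normalisation, droplet
digital PCR Poisson estimation, fold changes, cross-platform concordance,
and GWAS odds-ratio harmonisation.

Droplet digital PCR partitions a reaction into ~20,000 droplets of ~0.85 nL;
with template molecules Poisson-distributed over droplets, the fraction of
negative droplets estimates ``exp(-lambda)``, so

    lambda_hat = -ln(n_negative / n_total)
    copies/uL  = lambda_hat / droplet_volume_uL * dilution

with delta-method standard error ``SE(lambda_hat) = sqrt((e^lambda - 1)/n)``.

HTS counts are made comparable across sequencing pools by dividing by the
pool's mean per-sample total ("average reads in the pool"), and converted to
expression values by the endogenous-control ratio (target / GUSB).  The
control travels in a reduced reaction volume (5-10 %); an optional volume
fraction rescales it to full-reaction equivalents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ALL_SPECIES, SpliceForm, SpliceFormCountTable
from .simulate import DropletWell

__all__ = [
    "NormalizedExpression",
    "DdpcrEstimate",
    "SaturationError",
    "pool_normalize",
    "control_normalize",
    "ddpcr_concentration",
    "ddpcr_normalized_expression",
    "group_fold_change",
    "concordance",
    "harmonize_odds_ratios",
]


class SaturationError(ValueError):
    """All droplets positive: the Poisson estimate diverges."""


@dataclass
class NormalizedExpression:
    """A target/control expression ratio for one sample."""

    sample_id: str
    target: str  # species or TSS assay name
    value: float | None  # None when undefined (control missing/below LOD)
    log2_value: float | None = None
    flag: str = ""  # "", "undefined_control", "below_lod", ...

    def __post_init__(self) -> None:
        if self.value is not None:
            if self.value < 0:
                raise ValueError("expression value must be >= 0")
            if self.log2_value is None and self.value > 0:
                self.log2_value = math.log2(self.value)

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class DdpcrEstimate:
    """Poisson concentration estimate for one well."""

    concentration: float  # copies per uL of reaction
    lam: float  # mean molecules per droplet
    se_lambda: float
    below_lod: bool = False


def pool_normalize(
    counts: SpliceFormCountTable,
    pool_assignment: dict[str, str],
    include_unassigned: bool = True,
) -> SpliceFormCountTable:
    """Divide each sample's counts by its pool's mean per-sample total.

    Accounts for yield differences between sequencing pools; within a pool
    the normalised per-sample totals sum to the pool size.
    """
    samples = counts.df["sample_id"].unique()
    missing = [s for s in samples if s not in pool_assignment]
    if missing:
        raise ValueError(f"samples without pool assignment: {missing}")
    totals = counts.totals(include_unassigned=include_unassigned)
    pools = pd.Series({s: pool_assignment[s] for s in samples})
    pool_means = totals.groupby(pools).mean()
    if (pool_means <= 0).any():
        bad = list(pool_means[pool_means <= 0].index)
        raise ValueError(f"pools with zero total reads: {bad}")
    df = counts.df.copy()
    divisor = df["sample_id"].map(lambda s: pool_means[pool_assignment[s]])
    df["normalized_count"] = df["raw_count"] / divisor
    return SpliceFormCountTable(df)


def control_normalize(
    counts: SpliceFormCountTable,
    control_species: SpliceForm = SpliceForm.CONTROL,
    control_volume_fraction: float = 1.0,
    use_normalized: bool = True,
) -> list[NormalizedExpression]:
    """Express each ROI species as a ratio to the endogenous control.

    ``value = species / (control / control_volume_fraction)``: when only a
    fraction of the control reaction entered the pool, the observed control
    count is scaled back up to full-reaction equivalents.  Samples with a
    zero control count are flagged undefined, never reported as zero.
    """
    if not (0.0 < control_volume_fraction <= 1.0):
        raise ValueError("control_volume_fraction must be in (0, 1]")
    value_col = "normalized_count" if use_normalized else "raw_count"
    df = counts.df
    if use_normalized and df["normalized_count"].isna().all():
        value_col = "raw_count"
    out: list[NormalizedExpression] = []
    ctrl_name = str(SpliceForm(control_species))
    roi = [str(sp) for sp in ALL_SPECIES if str(sp) != ctrl_name]
    for sample_id, sub in df.groupby("sample_id", sort=True):
        by_species = dict(zip(sub["species"], sub[value_col]))
        ctrl = by_species.get(ctrl_name, 0)
        ctrl = 0.0 if pd.isna(ctrl) else float(ctrl)
        for sp in roi:
            if sp not in by_species:
                continue
            v = float(by_species[sp]) if pd.notna(by_species[sp]) else 0.0
            if ctrl <= 0:
                out.append(
                    NormalizedExpression(
                        sample_id, sp, None, flag="undefined_control"
                    )
                )
            else:
                effective_control = ctrl / control_volume_fraction
                out.append(
                    NormalizedExpression(sample_id, sp, v / effective_control)
                )
    return out


def ddpcr_concentration(
    well: DropletWell, reaction_dilution: float = 1.0
) -> DdpcrEstimate:
    """Poisson concentration estimate from a droplet well.

    Saturated wells (every droplet positive) are rejected: the estimator
    diverges.  Wells with no positive droplet return 0 flagged below the
    limit of detection.
    """
    if reaction_dilution <= 0:
        raise ValueError("reaction_dilution must be > 0")
    if well.n_positive == well.n_total:
        raise SaturationError(
            f"well {well.well_id}/{well.channel}: all {well.n_total} droplets "
            "positive; concentration not estimable"
        )
    if well.n_positive == 0:
        return DdpcrEstimate(0.0, 0.0, 0.0, below_lod=True)
    lam = -math.log((well.n_total - well.n_positive) / well.n_total)
    se = math.sqrt((math.exp(lam) - 1.0) / well.n_total)
    vol_ul = well.droplet_volume_nl * 1e-3
    return DdpcrEstimate(lam / vol_ul * reaction_dilution, lam, se)


def ddpcr_normalized_expression(
    target_well: DropletWell,
    control_well: DropletWell,
    sample_id: str = "",
    reaction_dilution: float = 1.0,
) -> NormalizedExpression:
    """Target concentration normalised to the endogenous control channel."""
    target = ddpcr_concentration(target_well, reaction_dilution)
    try:
        control = ddpcr_concentration(control_well, reaction_dilution)
    except SaturationError:
        return NormalizedExpression(
            sample_id, target_well.channel, None, flag="control_saturated"
        )
    if control.below_lod:
        return NormalizedExpression(
            sample_id, target_well.channel, None, flag="control_below_lod"
        )
    value = target.concentration / control.concentration
    return NormalizedExpression(
        sample_id,
        target_well.channel,
        value,
        flag="below_lod" if target.below_lod else "",
    )


def group_fold_change(
    expr: list[NormalizedExpression],
    grouping: dict[str, str],
    scale: str = "geometric",
) -> float:
    """Fold change of group B over group A.

    Geometric scale: ``2 ** (mean log2 B - mean log2 A)`` (the natural
    companion of log2-normalised expression); arithmetic: ``mean B / mean
    A``.  Groups are the two distinct labels in ``grouping`` sorted so that
    the second is compared against the first; undefined expressions are
    excluded.
    """
    if scale not in ("geometric", "arithmetic"):
        raise ValueError("scale must be 'geometric' or 'arithmetic'")
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise ValueError(f"grouping must define exactly 2 groups, got {labels}")
    a_label, b_label = labels
    groups: dict[str, list[float]] = {a_label: [], b_label: []}
    nonpositive = []
    for e in expr:
        if not e.defined or e.sample_id not in grouping:
            continue
        if scale == "geometric" and e.value <= 0:
            nonpositive.append(e.sample_id)
            continue
        groups[grouping[e.sample_id]].append(e.value)
    if nonpositive:
        raise ValueError(
            f"geometric fold change undefined for non-positive values in "
            f"samples {nonpositive}"
        )
    if not groups[a_label] or not groups[b_label]:
        raise ValueError("both groups must be non-empty")
    a = np.asarray(groups[a_label], dtype=float)
    b = np.asarray(groups[b_label], dtype=float)
    if scale == "geometric":
        return float(2.0 ** (np.mean(np.log2(b)) - np.mean(np.log2(a))))
    return float(b.mean() / a.mean())


def concordance(x, y) -> tuple[float, int]:
    """Spearman rank correlation between two paired measurement series.

    Pairs with a missing value in either series are dropped listwise;
    ties receive average ranks.  Returns ``(rho, n_pairs_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rho = stats.spearmanr(x, y).statistic
    return float(rho), n


def harmonize_odds_ratios(
    studies: pd.DataFrame,
    study_order: list[str] | None = None,
) -> pd.DataFrame:
    """Harmonise per-locus GWAS odds ratios to a consistent allele orientation.

    Input columns: ``locus, study, tested_allele, other_allele, odds_ratio``.
    Per locus the reference orientation is the *newest* study's risk allele
    (``study_order`` lists studies oldest to newest; by default input order
    of appearance is taken as chronological).  Studies tested on the
    opposite allele are flipped (OR <- 1/OR); if the reference study's OR in
    its own orientation is below 1 the whole locus is flipped so the
    consensus OR is >= 1.  Loci where a study's allele pair matches neither
    orientation are flagged and excluded.  Output is sorted by descending
    median OR across studies (missing studies excluded from the median).

    The operation is idempotent: harmonised input passes through unchanged.
    """
    required = {"locus", "study", "tested_allele", "other_allele", "odds_ratio"}
    missing = required - set(studies.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (studies["odds_ratio"] <= 0).any():
        raise ValueError("odds ratios must be > 0")
    if study_order is None:
        study_order = list(dict.fromkeys(studies["study"]))
    rank = {s: i for i, s in enumerate(study_order)}

    out_rows = []
    for locus, sub in studies.groupby("locus", sort=False):
        sub = sub.sort_values("study", key=lambda s: s.map(rank)).copy()
        ref = sub.iloc[-1]  # newest study
        # reference orientation: the newest study's risk allele
        if ref.odds_ratio >= 1.0:
            risk, other = ref.tested_allele, ref.other_allele
        else:
            risk, other = ref.other_allele, ref.tested_allele
        rows = []
        reconcilable = True
        for r in sub.itertuples():
            if r.tested_allele == risk and r.other_allele == other:
                orr = r.odds_ratio
            elif r.tested_allele == other and r.other_allele == risk:
                orr = 1.0 / r.odds_ratio
            else:
                reconcilable = False
                break
            rows.append(
                {
                    "locus": locus,
                    "study": r.study,
                    "tested_allele": risk,
                    "other_allele": other,
                    "odds_ratio": orr,
                }
            )
        if not reconcilable:
            continue  # flagged out: irreconcilable allele pair
        median = float(np.median([r["odds_ratio"] for r in rows]))
        for r in rows:
            r["median_or"] = median
        out_rows.extend(rows)
    columns = [
        "locus",
        "study",
        "tested_allele",
        "other_allele",
        "odds_ratio",
        "median_or",
    ]
    out = pd.DataFrame(out_rows, columns=columns)
    if out.empty:
        return out
    # within a locus keep chronological study order so the output's order of
    # appearance reflects the same chronology on a re-run (idempotence)
    out["_rank"] = out["study"].map(rank)
    out = out.sort_values(
        ["median_or", "locus", "_rank"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out[columns]
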