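"""Spike-in based estimation and correction of PCR/sequencing length bias.

Equimolar mixtures of synthetic fragments of the five amplicon species are
sequenced alongside the biological samples.  Departures of a species'
read share from the equimolar expectation 1/n measure the combined
amplification + bridge-PCR bias for that species; under geometric
amplification with per-cycle efficiency e the expected factor ratio between
two species is ((1+e_i)/(1+e_j))**n_cycles.

Within each mixture the per-species factor is ``share * n_species``; the
pooled factor is the geometric mean across mixtures (factors are ratios),
renormalised so the factors' geometric mean over species is 1.  Stability of
the per-mixture factors across a 16-fold template range — summarised as a
per-species coefficient of variation — is the calibration's QC criterion.

Correction is per-species multiplicative (count / factor).  A length fit
(log factor vs amplicon length) is available as a diagnostic only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import ALL_SPECIES, SpliceForm, SpliceFormCountTable
from .simulate import MixtureManifest

__all__ = ["BiasModel", "CalibrationError", "estimate_bias", "apply_bias_correction"]


class CalibrationError(ValueError):
    pass


@dataclass
class BiasModel:
    """Per-species amplification bias factors.

    ``factors`` have geometric mean 1 over species.  ``per_mixture_factors``
    is a mixtures x species frame of the individual (renormalised)
    estimates, ``consistency_cv`` their per-species coefficient of
    variation, and ``length_fit`` an optional (slope, intercept) of
    log(factor) against amplicon length.
    """

    factors: dict[SpliceForm, float]
    per_mixture_factors: pd.DataFrame
    consistency_cv: dict[SpliceForm, float]
    length_fit: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()), dtype=float)
        if (vals <= 0).any():
            raise CalibrationError("bias factors must be positive")
        gm = float(np.exp(np.mean(np.log(vals))))
        if abs(gm - 1.0) > 1e-6:
            raise CalibrationError(f"factors must have geometric mean 1, got {gm}")

    def qc_pass(self, cv_threshold: float = 0.2) -> bool:
        """True when every species' cross-mixture factor CV is below threshold."""
        worst = max(self.consistency_cv.values())
        if worst >= cv_threshold:
            warnings.warn(
                f"bias factor consistency CV {worst:.3f} exceeds threshold "
                f"{cv_threshold}; spike-in calibration may be unreliable",
                stacklevel=2,
            )
            return False
        return True

    def to_tsv(self, path: str | Path) -> None:
        n_mix = len(self.per_mixture_factors)
        pd.DataFrame(
            {
                "species": [str(sp) for sp in self.factors],
                "factor": list(self.factors.values()),
                "cv": [self.consistency_cv[sp] for sp in self.factors],
                "n_mixtures_used": [
                    int(self.per_mixture_factors[str(sp)].notna().sum())
                    if str(sp) in self.per_mixture_factors
                    else n_mix
                    for sp in self.factors
                ],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasModel":
        df = pd.read_csv(path, sep="\t")
        factors = {SpliceForm(r.species): float(r.factor) for r in df.itertuples()}
        cv = {SpliceForm(r.species): float(r.cv) for r in df.itertuples()}
        return cls(
            factors=factors,
            per_mixture_factors=pd.DataFrame(
                [{str(sp): f for sp, f in factors.items()}]
            ),
            consistency_cv=cv,
        )


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def estimate_bias(
    spikein_counts: SpliceFormCountTable,
    manifests: list[MixtureManifest],
    species_lengths: dict[SpliceForm, int] | None = None,
) -> BiasModel:
    """Estimate per-species bias factors from equimolar mixture counts.

    ``spikein_counts`` holds one row set per mixture (sample_id =
    mixture_id).  A species with zero reads in some mixture is excluded
    from that mixture with a warning; a species with zero reads everywhere
    aborts the estimation.
    """
    if not manifests:
        raise CalibrationError("at least one mixture is required")
    species = [sp for sp in ALL_SPECIES]
    rows = []
    for manifest in manifests:
        counts = spikein_counts.counts_for(manifest.mixture_id)
        if not counts:
            raise CalibrationError(f"no counts for mixture {manifest.mixture_id!r}")
        obs = {}
        for sp in manifest.species:
            c = counts.get(str(sp), 0)
            if c == 0:
                warnings.warn(
                    f"mixture {manifest.mixture_id!r}: species {sp} has zero "
                    "reads; excluded from this mixture",
                    stacklevel=2,
                )
                obs[sp] = np.nan
            else:
                obs[sp] = float(c)
        total = np.nansum(list(obs.values()))
        n_obs = sum(1 for v in obs.values() if np.isfinite(v))
        if n_obs == 0:
            raise CalibrationError(
                f"mixture {manifest.mixture_id!r} has no usable species"
            )
        # share relative to equimolar expectation among observed species,
        # renormalised within the mixture to geometric mean 1 so factors are
        # comparable across mixtures regardless of depth or missingness
        factors = {
            sp: (v / total) * n_obs if np.isfinite(v) else np.nan
            for sp, v in obs.items()
        }
        finite = np.array([v for v in factors.values() if np.isfinite(v)])
        gm = _geomean(finite)
        rows.append(
            {
                "mixture_id": manifest.mixture_id,
                **{str(sp): v / gm for sp, v in factors.items()},
            }
        )
    per_mix = pd.DataFrame(rows).set_index("mixture_id")

    pooled: dict[SpliceForm, float] = {}
    cv: dict[SpliceForm, float] = {}
    for sp in species:
        col = per_mix[str(sp)].dropna()
        if col.empty:
            raise CalibrationError(f"species {sp} has zero reads in every mixture")
        pooled[sp] = _geomean(col.to_numpy())
        cv[sp] = float(col.std(ddof=1) / col.mean()) if len(col) > 1 else 0.0
    gm = _geomean(np.array(list(pooled.values())))
    pooled = {sp: f / gm for sp, f in pooled.items()}

    length_fit = None
    if species_lengths:
        xs = np.array([species_lengths[sp] for sp in species], dtype=float)
        ys = np.log(np.array([pooled[sp] for sp in species]))
        fit = stats.linregress(xs, ys)
        length_fit = (float(fit.slope), float(fit.intercept))

    return BiasModel(
        factors=pooled,
        per_mixture_factors=per_mix.reset_index(),
        consistency_cv=cv,
        length_fit=length_fit,
    )


def apply_bias_correction(
    counts: SpliceFormCountTable, model: BiasModel
) -> SpliceFormCountTable:
    """Divide each species' counts by its bias factor.

    The corrected value lands in ``normalized_count`` (correcting the
    already-normalised value when one is present, the raw count otherwise);
    UNASSIGNED rows pass through untouched.  Raises when a species present
    in the table has no factor.
    """
    df = counts.df.copy()
    factor_by_name = {str(sp): f for sp, f in model.factors.items()}
    unassigned = str(SpliceForm.UNASSIGNED)
    missing = sorted(
        set(df["species"]) - set(factor_by_name) - {unassigned}
    )
    if missing:
        raise CalibrationError(f"no bias factor for species: {missing}")
    base = df["normalized_count"].where(
        df["normalized_count"].notna(), df["raw_count"].astype(float)
    )
    fac = df["species"].map(factor_by_name)
    corrected = base / fac
    keep = df["species"] == unassigned
    df["normalized_count"] = base.where(keep, corrected)
    df.loc[~keep, "corrected"] = True
    # UNASSIGNED rows keep their previous normalisation state
    df.loc[keep, "normalized_count"] = counts.df.loc[keep, "normalized_count"]
    return SpliceFormCountTable(df)
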