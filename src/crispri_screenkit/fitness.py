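"""Fitness inference from pooled competitive-growth barcode counts.

Each barcode marks an independently transformed lineage. During induced
competitive growth a lineage with selection coefficient ``s`` changes
relative abundance by a factor ``s`` per population doubling, so counts
follow a log-linear trajectory in generations. Per barcode we fit a
negative-binomial GLM with log link,

    log E[count] = log(size_factor) + b0 + b_gens * gens + b_culture,

and report the fitness score ``b_gens / ln 2`` — log2 change in relative
abundance per doubling: 0 is neutral, -1 is a non-replicating lineage whose
(persistent) plasmid halves in frequency each generation. Guide-level
fitness is the inverse-variance weighted mean over the guide's barcodes,
and the active-guide threshold is the 5th percentile of the scaffold-only
negative-control fitness distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

LN2 = np.log(2.0)

#: population-doubling schedule of the growth screen (pre-induction = 0)
DEFAULT_GENS = (0.0, 3.75, 7.5, 11.25)

MIN_PREINDUCTION_READS = 64
DISPERSION_FLOOR = 1e-8


@dataclass
class BarcodeFitness:
    barcode: str
    slope: float  # log2 relative-abundance change per doubling
    se: float
    converged: bool
    dispersion: float = 0.0


def check_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata (index sample_id, columns gens, culture)."""
    for col in ("gens", "culture"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks a '{col}' column")
    gens = pd.to_numeric(meta["gens"], errors="coerce")
    if gens.isna().any():
        bad = meta.index[gens.isna()].tolist()
        raise ValueError(f"non-numeric gens values for samples {bad}")
    if (gens < 0).any():
        raise ValueError("gens values must be non-negative")
    out = meta.copy()
    out["gens"] = gens.astype(float)
    return out


def filter_preinduction(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_reads: int = MIN_PREINDUCTION_READS,
) -> pd.DataFrame:
    """Keep barcodes with >= ``min_reads`` pre-induction reads in >= 1 culture."""
    meta = check_meta(meta)
    pre_samples = meta.index[meta["gens"] == 0.0]
    if len(pre_samples) == 0:
        raise ValueError("no pre-induction (gens = 0) samples in metadata")
    keep = (counts[pre_samples] >= min_reads).any(axis=1)
    return counts[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors, geometric mean 1.

    The reference per barcode is the geometric mean across samples over
    barcodes with no zero counts; each sample's factor is the median ratio
    of its counts to the reference. When no barcode is all-nonzero, falls
    back to total-count ratios with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if nonzero.any():
        sub = mat[nonzero]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    else:
        warnings.warn(
            "no barcode with nonzero counts in all samples; "
            "falling back to total-count size factors"
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: empty samples present")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _design_matrix(meta: pd.DataFrame) -> np.ndarray:
    cultures = sorted(meta["culture"].astype(str).unique())
    cols = [np.ones(len(meta)), meta["gens"].to_numpy(dtype=float)]
    for culture in cultures[1:]:
        cols.append((meta["culture"].astype(str) == culture).to_numpy(dtype=float))
    return np.column_stack(cols)


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments NB dispersion: solve sum((y-mu)^2 - mu) = a*sum(mu^2)."""
    denom = float(np.sum(mu**2))
    if denom <= 0:
        return DISPERSION_FLOOR
    alpha = float(np.sum((y - mu) ** 2 - mu)) / denom
    return max(alpha, DISPERSION_FLOOR)


def fit_barcode_glm(
    counts_row: pd.Series,
    meta: pd.DataFrame,
    size_factors: Optional[pd.Series] = None,
    dispersion: Optional[float] = None,
) -> BarcodeFitness:
    """Negative-binomial fit of one barcode's count trajectory.

    ``counts_row`` is indexed by sample_id; ``meta`` must cover those
    samples. Cultures in which the barcode has no reads at all are dropped
    from the fit (together with their indicator) rather than driving the
    culture coefficient to -infinity. Dispersion defaults to a per-barcode
    method-of-moments estimate from a Poisson pre-fit, floored at 1e-8.
    """
    meta = check_meta(meta.loc[counts_row.index])
    sf = (
        pd.Series(1.0, index=counts_row.index)
        if size_factors is None
        else size_factors.loc[counts_row.index]
    )
    y = counts_row.to_numpy(dtype=float)
    # drop cultures where the barcode was never observed
    culture = meta["culture"].astype(str)
    seen = {c for c in culture.unique() if y[(culture == c).to_numpy()].sum() > 0}
    if seen and len(seen) < culture.nunique():
        keep = culture.isin(seen).to_numpy()
        y, meta, sf = y[keep], meta[keep], sf[keep]
    barcode = str(counts_row.name)
    if len(y) < 4 or meta["gens"].nunique() < 2:
        return BarcodeFitness(barcode, np.nan, np.nan, converged=False)
    X = _design_matrix(meta)
    offset = np.log(sf.to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if dispersion is None:
                pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
                dispersion = _moment_dispersion(y, pois.mu, X.shape[1])
            res = sm.GLM(
                y,
                X,
                family=sm.families.NegativeBinomial(alpha=dispersion),
                offset=offset,
            ).fit()
        converged = bool(getattr(res, "converged", True))
        slope = float(res.params[1]) / LN2
        se = float(res.bse[1]) / LN2
        if not np.isfinite(slope) or not np.isfinite(se) or se <= 0:
            converged = False
    except Exception:
        return BarcodeFitness(barcode, np.nan, np.nan, False, dispersion or 0.0)
    return BarcodeFitness(barcode, slope, se, converged, dispersion)


def fit_all_barcodes(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    normalize: bool = True,
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Fit every barcode row; returns a barcode-indexed fitness table."""
    sf = size_factors(counts) if normalize else None
    fits = [fit_barcode_glm(counts.loc[bc], meta, sf, dispersion)
            for bc in counts.index]
    return pd.DataFrame(
        {
            "barcode": [f.barcode for f in fits],
            "slope": [f.slope for f in fits],
            "se": [f.se for f in fits],
            "converged": [f.converged for f in fits],
            "dispersion": [f.dispersion for f in fits],
        }
    ).set_index("barcode")


def aggregate_guide(barcode_fits: pd.DataFrame) -> tuple[float, float, int]:
    """Inverse-variance weighted mean of converged barcode slopes.

    Returns (fitness, se, n_barcodes); raises when no barcode converged.
    """
    good = barcode_fits[barcode_fits["converged"] & (barcode_fits["se"] > 0)]
    if len(good) == 0:
        raise ValueError("no converged barcode fits to aggregate")
    w = 1.0 / good["se"].to_numpy() ** 2
    slopes = good["slope"].to_numpy()
    fitness = float(np.sum(w * slopes) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return fitness, se, len(good)


def aggregate_guides(
    barcode_fits: pd.DataFrame, barcode_to_guide: Mapping[str, str]
) -> pd.DataFrame:
    """Guide-level fitness table from barcode fits and the assignment map.

    Guides with zero converged barcodes are omitted.
    """
    fits = barcode_fits.copy()
    fits["guide_id"] = fits.index.map(lambda bc: barcode_to_guide.get(bc))
    fits = fits[fits["guide_id"].notna()]
    rows = []
    for guide_id, group in fits.groupby("guide_id"):
        try:
            fitness, se, n = aggregate_guide(group)
        except ValueError:
            continue
        rows.append(
            {"guide_id": guide_id, "fitness": fitness, "se": se, "n_barcodes": n}
        )
    return pd.DataFrame(rows).set_index("guide_id")


def control_threshold(
    control_fits: Sequence[float], percentile: float = 5.0, min_controls: int = 20
) -> float:
    """Active-guide fitness threshold: 5th percentile of negative controls."""
    values = np.asarray(control_fits, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_controls:
        raise ValueError(
            f"need at least {min_controls} negative-control fitness values, "
            f"got {len(values)}"
        )
    return float(np.percentile(values, percentile))
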