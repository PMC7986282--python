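"""Guide-activity modeling from target position, occupancy, and sequence.

The position dependence of CRISPRi is captured empirically by a local
(loess) regression of guide fitness against the target-center offset from
the TSS over the [-220, +20] design window; its prediction (OffsetPred)
feeds, together with the minimum nucleosome occupancy in a 33-nt window
around the target (ODM) and 20 categorical protospacer base identities, a
logistic regression for the active/inactive label. Models are evaluated by
k-fold cross-validation (refitting both stages per fold), scored on
held-out guides as logits, and checked for calibration: a guide scoring at
logit 0 should be active about half the time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .genome import AccessibilityTrack

LOESS_ALPHA = 0.25
OFFSET_RANGE = (-220, 20)
ODM_FLANK = 5  # flanking nt on each side of the 23-nt target
SEQ_BASES = ("C", "G", "T")  # dummy contrasts; A is the reference level
RIDGE_PENALTY = 1e-4


def _loess_predict(
    x: np.ndarray, y: np.ndarray, x0: np.ndarray, alpha: float
) -> np.ndarray:
    """Tricube-weighted local linear regression predictions at ``x0``.

    The span window is the ceil(alpha * n) nearest points; queries outside
    the data range are clamped to the boundary fit. No robustness
    iterations.
    """
    n = len(x)
    r = max(2, int(np.ceil(alpha * n)))
    lo, hi = float(np.min(x)), float(np.max(x))
    out = np.empty(len(x0))
    for j, q in enumerate(np.clip(np.asarray(x0, dtype=float), lo, hi)):
        d = np.abs(x - q)
        if n > r:
            idx = np.argpartition(d, r - 1)[:r]
        else:
            idx = np.arange(n)
        xi, yi, di = x[idx], y[idx], d[idx]
        dmax = di.max()
        if dmax == 0:
            out[j] = float(np.mean(yi))
            continue
        w = (1.0 - (di / dmax) ** 3) ** 3
        sw = w.sum()
        xbar = np.sum(w * xi) / sw
        ybar = np.sum(w * yi) / sw
        sxx = np.sum(w * (xi - xbar) ** 2)
        if sxx <= 1e-12:
            out[j] = ybar
        else:
            slope = np.sum(w * (xi - xbar) * (yi - ybar)) / sxx
            out[j] = ybar + slope * (q - xbar)
    return out


@dataclass
class PositionCurve:
    """Fitted loess of fitness against TSS offset (optionally per strand)."""

    x: np.ndarray
    y: np.ndarray
    alpha: float = LOESS_ALPHA
    strand: Optional[np.ndarray] = None  # per-point strand for the variant

    def predict(self, offsets, strand=None) -> np.ndarray:
        offsets = np.asarray(offsets, dtype=float)
        if self.strand is None or strand is None:
            return _loess_predict(self.x, self.y, offsets, self.alpha)
        strand = np.asarray(strand)
        out = np.empty(len(offsets))
        for s in np.unique(strand):
            sel_fit = self.strand == s
            sel_q = strand == s
            out[sel_q] = _loess_predict(
                self.x[sel_fit], self.y[sel_fit], offsets[sel_q], self.alpha
            )
        return out


def fit_position_loess(
    offsets: Sequence[float],
    fitness: Sequence[float],
    alpha: float = LOESS_ALPHA,
    strand: Optional[Sequence[str]] = None,
) -> PositionCurve:
    """Fit the position-activity curve over the design window.

    ``strand`` switches on the strand-specific variant (two curves); the
    strand-independent curve is the default model.
    """
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(fitness, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 (offset, fitness) points")
    if int(np.ceil(alpha * len(x))) < 2:
        raise ValueError("span too small for the number of points")
    s = None if strand is None else np.asarray(strand)
    return PositionCurve(x=x, y=y, alpha=alpha, strand=s)


def min_occupancy_window(
    track: AccessibilityTrack,
    chrom: str,
    target_start: int,
    target_end: int,
    flank: int = ODM_FLANK,
) -> float:
    """Lowest occupancy in the 33-nt window: target plus 5 nt each side."""
    if track.kind != "occupancy":
        raise ValueError("ODM feature requires an occupancy track")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = track.window_values(chrom, target_start - flank, target_end + flank)
    return float(np.min(vals)) if len(vals) else 1.0


def build_features(
    guides: pd.DataFrame,
    fitness_table: pd.DataFrame,
    occupancy_track: Optional[AccessibilityTrack],
    threshold: float,
    curve: Optional[PositionCurve] = None,
) -> pd.DataFrame:
    """Assemble the per-guide feature table.

    ``guides`` is the design table (guide_id, chrom, 1-based target
    start/end, center_offset, protospacer); ``fitness_table`` is the
    guide-level fitness table. Guides lacking occupancy data get odm = 1.0
    (assume occupied). ``active`` is fitness below the negative-control
    threshold. OffsetPred is filled when a curve is supplied; during
    cross-validation it is recomputed per fold instead.
    """
    df = guides.set_index("guide_id") if "guide_id" in guides.columns else guides
    df = df.join(fitness_table[["fitness"]], how="inner")
    odm = np.ones(len(df))
    if occupancy_track is not None:
        for i, (start, end, chrom) in enumerate(
            zip(df["target_start"], df["target_end"], df["chrom"])
        ):
            odm[i] = min_occupancy_window(occupancy_track, chrom, int(start) - 1, int(end))
    out = pd.DataFrame(
        {
            "offset": df["center_offset"].astype(int),
            "odm": odm,
            "protospacer": df["protospacer"],
            "fitness": df["fitness"].astype(float),
        },
        index=df.index,
    )
    out["active"] = out["fitness"] < threshold
    if curve is not None:
        out["offset_pred"] = curve.predict(out["offset"].to_numpy())
    return out


def design_matrix(
    features: pd.DataFrame,
    include_odm: bool = True,
    include_seq: bool = True,
    include_atac: bool = False,
) -> pd.DataFrame:
    """Logistic design matrix: intercept, OffsetPred, ODM, base dummies."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(features))}
    cols["offset_pred"] = features["offset_pred"].to_numpy(dtype=float)
    if include_odm:
        cols["odm"] = features["odm"].to_numpy(dtype=float)
    if include_atac:
        cols["atac"] = features["atac"].to_numpy(dtype=float)
    if include_seq:
        seqs = features["protospacer"].str.upper()
        for pos in range(20):
            at_pos = seqs.str[pos]
            unseen = ~at_pos.isin(("A",) + SEQ_BASES)
            if unseen.any():
                warnings.warn(
                    f"unseen base category at protospacer position {pos + 1}; "
                    "treated as the reference level"
                )
            for base in SEQ_BASES:
                cols[f"nt{pos + 1:02d}_{base}"] = (at_pos == base).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=features.index)


@dataclass
class ActivityModel:
    """Position curve plus logistic coefficients for guide activity."""

    curve: PositionCurve
    params: pd.Series
    bse: Optional[pd.Series] = None
    include_odm: bool = True
    include_seq: bool = True
    include_atac: bool = False
    regularized: bool = False
    k_folds: Optional[int] = None
    seed: Optional[int] = None


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.Series, Optional[pd.Series], bool]:
    """Maximum-likelihood logistic fit with a weak-ridge separation fallback."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params, bse = res.params, res.bse
        if np.isfinite(params).all() and np.isfinite(bse).all() and (
            np.abs(params).max() < 1e3
        ):
            return params, bse, False
    except Exception:
        pass
    warnings.warn(
        "logistic fit unstable (possible perfect separation); "
        f"refitting with L2 penalty {RIDGE_PENALTY}"
    )
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(
        penalty="l2", C=1.0 / RIDGE_PENALTY, fit_intercept=False, max_iter=2000
    )
    lr.fit(X.to_numpy(), y.astype(int))
    return pd.Series(lr.coef_[0], index=X.columns), None, True


def fit_logistic(
    features: pd.DataFrame,
    curve: PositionCurve,
    include_odm: bool = True,
    include_seq: bool = True,
    include_atac: bool = False,
) -> ActivityModel:
    """Fit ``active ~ OffsetPred + ODM + nt01 + ... + nt20``.

    ``features`` must carry an ``offset_pred`` column computed from
    ``curve`` (or have one filled in here when absent).
    """
    feats = features.copy()
    if "offset_pred" not in feats.columns:
        feats["offset_pred"] = curve.predict(feats["offset"].to_numpy())
    y = feats["active"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both activity classes must be present")
    X = design_matrix(feats, include_odm, include_seq, include_atac)
    params, bse, regularized = _fit_logit(X, y)
    return ActivityModel(
        curve=curve,
        params=params,
        bse=bse,
        include_odm=include_odm,
        include_seq=include_seq,
        include_atac=include_atac,
        regularized=regularized,
    )


def score_guides(model: ActivityModel, features: pd.DataFrame) -> pd.Series:
    """Logit activity scores from the model's linear predictor."""
    feats = features.copy()
    feats["offset_pred"] = model.curve.predict(feats["offset"].to_numpy())
    X = design_matrix(
        feats, model.include_odm, model.include_seq, model.include_atac
    )
    X = X.reindex(columns=model.params.index, fill_value=0.0)
    return pd.Series(X.to_numpy() @ model.params.to_numpy(), index=feats.index,
                     name="score")


def auc_score(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVResult:
    auc: float
    scores: pd.Series  # pooled held-out logits, aligned to the feature index
    k: int
    seed: int


def crossvalidate_auc(
    features: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    alpha: float = LOESS_ALPHA,
    include_odm: bool = True,
    include_seq: bool = True,
    include_atac: bool = False,
) -> CVResult:
    """k-fold CV refitting both loess and logistic stages per fold.

    Folds are a seeded random partition of guides; folds left with a single
    activity class in training are merged into the next fold with a
    warning. Returns the pooled held-out AUC and scores.
    """
    n = len(features)
    if n < k:
        raise ValueError("fewer guides than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[i::k] for i in range(k)]
    # merge folds whose training complement would be single-class
    y_all = features["active"].to_numpy(dtype=bool)
    merged: list[np.ndarray] = []
    for fold in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[fold] = False
        if len(np.unique(y_all[train_mask])) < 2:
            warnings.warn("fold with single-class training set merged with neighbor")
            if merged:
                merged[-1] = np.concatenate([merged[-1], fold])
                continue
        merged.append(fold)
    scores = pd.Series(np.nan, index=features.index, name="score")
    for fold in merged:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[fold] = True
        train = features.iloc[~test_mask]
        test = features.iloc[test_mask]
        curve = fit_position_loess(
            train["offset"].to_numpy(), train["fitness"].to_numpy(), alpha
        )
        train = train.copy()
        train["offset_pred"] = curve.predict(train["offset"].to_numpy())
        model = fit_logistic(
            train, curve, include_odm, include_seq, include_atac
        )
        scores.iloc[test_mask] = score_guides(model, test).to_numpy()
    auc = auc_score(scores.to_numpy(), y_all)
    return CVResult(auc=auc, scores=scores, k=k, seed=seed)


def calibration_check(
    scores: Sequence[float],
    fitness: Sequence[float],
    threshold: float,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Binned calibration table: median fitness and active fraction vs score.

    Bins are ``bin_width`` logits wide and centered so one bin is centered
    on logit 0; empty bins are skipped. The returned table flags the
    logit-0 bin, whose active fraction should be near 0.5 for a calibrated
    model.
    """
    scores = np.asarray(scores, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    active = fitness < threshold
    centers = np.round(scores / bin_width) * bin_width
    rows = []
    for c in np.unique(centers):
        sel = centers == c
        rows.append(
            {
                "bin_center": float(c),
                "n": int(sel.sum()),
                "median_fitness": float(np.median(fitness[sel])),
                "active_fraction": float(active[sel].mean()),
                "is_logit0_bin": bool(abs(c) < bin_width / 2),
            }
        )
    return pd.DataFrame(rows)
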