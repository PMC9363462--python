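"""Feature-importance analysis of enrichment with Random-Forest regression.

Peptides are one-hot encoded over their randomized positions (20 indicator
columns per position, deterministic ordering), a Random-Forest regressor is
trained to predict enrichment under k-fold cross-validation, and permutation
importance — the increase in held-out mean-squared error when one feature
column is shuffled — is averaged over folds x repeats.  The Pearson
correlation of each raw indicator column with enrichment supplies the sign:
whether a residue at a position is associated with an increase (+) or
decrease (-) of enrichment.

Companion analyses group peptides by the number of hydrophobic residues in
the randomized region and by polar/nonpolar residue at each position, with
two-sided Welch t-tests (alpha = 0.01) between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .library_design import AMINO_ACIDS, LibraryDesign, rel_to_abs

__all__ = [
    "HYDROPHOBIC_RESIDUES",
    "POLAR_RESIDUES",
    "CVFit",
    "GroupComparison",
    "fit_rf_cv",
    "hydrophobic_count_analysis",
    "hypertune",
    "one_hot_encode",
    "permutation_importance_cv",
    "polarity_by_position",
    "welch_t",
]

# Cys is deliberately in both sets: it is a small borderline-polar residue
# with a hydrophobic thiol; both groupings are defensible and configurable.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWC")
POLAR_RESIDUES = frozenset("STYNQCDEKRH")


def one_hot_encode(peptides, design: LibraryDesign) -> pd.DataFrame:
    """One-hot indicators over randomized positions.

    Columns are ``"{rel:+d}:{residue}"`` ordered by relative position
    (ascending) then residue (alphabetical); each peptide's per-position
    block sums to exactly 1.
    """
    peptides = list(peptides)
    rels = design.randomized_rel
    cols = [f"{rel:+d}:{aa}" for rel in rels for aa in AMINO_ACIDS]
    if not peptides:
        return pd.DataFrame(columns=cols)
    arr = np.frombuffer("".join(peptides).encode(), np.uint8).reshape(
        len(peptides), design.length
    )
    blocks = []
    for rel in rels:
        col = arr[:, rel_to_abs(design, rel)]
        block = col[:, None] == np.frombuffer(AMINO_ACIDS.encode(), np.uint8)
        if not block.any(axis=1).all():
            bad = peptides[int(np.flatnonzero(~block.any(axis=1))[0])]
            raise ValueError(
                f"peptide {bad!r}: residue outside the 20-letter alphabet "
                f"at relative position {rel:+d}"
            )
        blocks.append(block)
    X = np.concatenate(blocks, axis=1).astype(np.float64)
    return pd.DataFrame(X, columns=cols, index=pd.Index(peptides, name="peptide"))


@dataclass
class CVFit:
    """k-fold cross-validated Random-Forest fit."""

    models: list
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]
    fold_mse: np.ndarray

    @property
    def mean_mse(self) -> float:
        return float(self.fold_mse.mean())


def fit_rf_cv(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 10,
    n_estimators: int = 200,
    seed: int = 0,
    **rf_params,
) -> CVFit:
    """Train one Random-Forest regressor per CV fold.

    Fold assignment and tree growth are deterministic under ``seed``.
    """
    Xv = np.asarray(X, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if len(Xv) < k:
        raise ValueError(f"{len(Xv)} rows < {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    models, trains, tests, mses = [], [], [], []
    for fold, (tr, te) in enumerate(kf.split(Xv)):
        model = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=seed + 1000 * (fold + 1),
            n_jobs=1,
            **rf_params,
        )
        model.fit(Xv[tr], yv[tr])
        pred = model.predict(Xv[te])
        models.append(model)
        trains.append(tr)
        tests.append(te)
        mses.append(float(np.mean((pred - yv[te]) ** 2)))
    return CVFit(models, trains, tests, np.array(mses))


def hypertune(
    X: pd.DataFrame,
    y: pd.Series,
    n_iter: int = 25,
    k: int = 10,
    n_estimators: int = 200,
    seed: int = 0,
    grid: dict | None = None,
) -> tuple[dict, float]:
    """Randomized search over tree-shape parameters, scored by CV MSE.

    The default grid covers depth, features-per-split and leaf size.
    Returns ``(best_params, best_cv_mse)``; the running minimum over the
    seeded candidate stream is monotone in ``n_iter``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if grid is None:
        grid = {
            "max_depth": [None, 5, 10, 20, 40],
            "max_features": ["sqrt", 0.3, 0.5, 1.0],
            "min_samples_leaf": [1, 2, 5, 10],
        }
    rng = np.random.default_rng(seed)
    best_params, best_mse = None, np.inf
    for _ in range(n_iter):
        cand = {
            key: values[rng.integers(len(values))]
            for key, values in grid.items()
        }
        fit = fit_rf_cv(
            X, y, k=k, n_estimators=n_estimators, seed=seed, **cand
        )
        if fit.mean_mse < best_mse:
            best_params, best_mse = cand, fit.mean_mse
    return best_params, float(best_mse)


def permutation_importance_cv(
    fit: CVFit,
    X: pd.DataFrame,
    y: pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out permutation importance averaged over folds x repeats.

    For each feature the importance is the mean increase in a fold's
    held-out MSE when that column is permuted; the dispersion (sd) is taken
    over all fold x repeat values.  Signs come from the Pearson correlation
    of the raw feature column with the response over all rows (empty for
    zero-variance columns).

    Returns a DataFrame sorted by ``rank`` with columns: feature, position,
    residue, importance, importance_sd, pearson_r, sign, rank.
    """
    Xv = np.asarray(X, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    n_feat = Xv.shape[1]
    rng = np.random.default_rng(seed)
    values = np.empty((len(fit.models), n_repeats, n_feat))
    for f, (model, te) in enumerate(zip(fit.models, fit.test_indices)):
        Xt, yt = Xv[te], yv[te]
        base_mse = float(np.mean((model.predict(Xt) - yt) ** 2))
        # one batched predict per fold: all repeats x features stacked
        stacked = np.tile(Xt, (n_repeats * n_feat, 1, 1))
        for r in range(n_repeats):
            for j in range(n_feat):
                perm = rng.permutation(len(yt))
                stacked[r * n_feat + j, :, j] = Xt[perm, j]
        preds = model.predict(stacked.reshape(-1, n_feat)).reshape(
            n_repeats * n_feat, len(yt)
        )
        mses = np.mean((preds - yt) ** 2, axis=1)
        values[f] = mses.reshape(n_repeats, n_feat) - base_mse

    flat = values.reshape(-1, n_feat)
    mean_imp = flat.mean(axis=0)
    sd_imp = flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(n_feat)

    with np.errstate(invalid="ignore", divide="ignore"):
        xc = Xv - Xv.mean(axis=0)
        yc = yv - yv.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, np.nan)

    features = list(X.columns)
    positions = [f.split(":")[0] for f in features]
    residues = [f.split(":")[1] for f in features]
    out = pd.DataFrame(
        {
            "feature": features,
            "position": positions,
            "residue": residues,
            "importance": mean_imp,
            "importance_sd": sd_imp,
            "pearson_r": r,
            "sign": ["" if np.isnan(v) else ("+" if v >= 0 else "-") for v in r],
        }
    )
    out = out.sort_values(
        by=["importance", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate convention: both samples constant with equal means ->
    (0.0, 1.0); constant with different means -> (+/-inf, 0.0).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class GroupComparison:
    """Summary statistics and pairwise Welch tests over peptide groups."""

    grouping: str
    groups: pd.DataFrame  # label, n, median, q1, q3
    tests: pd.DataFrame  # group_a, group_b, t, p, significant
    alpha: float = 0.01
    notes: list[str] = field(default_factory=list)


def _summaries(grouping: str, samples: dict, alpha: float, notes: list[str]):
    rows = [
        {
            "label": label,
            "n": len(vals),
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "q1": float(np.percentile(vals, 25)) if len(vals) else np.nan,
            "q3": float(np.percentile(vals, 75)) if len(vals) else np.nan,
        }
        for label, vals in samples.items()
    ]
    tests = []
    labels = list(samples)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            va, vb = samples[la], samples[lb]
            if len(va) < 2 or len(vb) < 2:
                notes.append(f"skipped {la} vs {lb}: a group has n < 2")
                continue
            t, p = welch_t(va, vb)
            tests.append(
                {
                    "group_a": la,
                    "group_b": lb,
                    "t": t,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return GroupComparison(
        grouping=grouping,
        groups=pd.DataFrame(rows),
        tests=pd.DataFrame(
            tests, columns=["group_a", "group_b", "t", "p", "significant"]
        ),
        alpha=alpha,
        notes=notes,
    )


def hydrophobic_count_analysis(
    peptides,
    ef,
    design: LibraryDesign,
    hydrophobic_set=HYDROPHOBIC_RESIDUES,
    alpha: float = 0.01,
) -> GroupComparison:
    """Group peptides by how many randomized residues are hydrophobic."""
    peptides = list(peptides)
    ef = np.asarray(ef, float)
    abs_pos = [rel_to_abs(design, r) for r in design.randomized_rel]
    counts = np.array(
        [sum(p[i] in hydrophobic_set for i in abs_pos) for p in peptides]
    )
    samples = {
        str(k): ef[counts == k] for k in range(len(abs_pos) + 1)
    }
    samples = {k: v for k, v in samples.items() if len(v) > 0}
    return _summaries("hydrophobic_count", samples, alpha, [])


def polarity_by_position(
    peptides,
    ef,
    design: LibraryDesign,
    polar_set=POLAR_RESIDUES,
    alpha: float = 0.01,
) -> dict[int, GroupComparison]:
    """Polar vs nonpolar split of enrichment at each randomized position."""
    peptides = list(peptides)
    ef = np.asarray(ef, float)
    out: dict[int, GroupComparison] = {}
    for rel in design.randomized_rel:
        pos = rel_to_abs(design, rel)
        polar = np.array([p[pos] in polar_set for p in peptides])
        notes: list[str] = []
        samples = {"P": ef[polar], "NP": ef[~polar]}
        if len(samples["P"]) == 0 or len(samples["NP"]) == 0:
            notes.append(
                f"position {rel:+d}: degenerate split, no test performed"
            )
            samples = {k: v for k, v in samples.items() if len(v) > 0}
        out[rel] = _summaries(f"polarity@{rel:+d}", samples, alpha, notes)
    return out
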