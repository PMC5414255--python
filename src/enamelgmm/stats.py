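"""Shape-space statistics.

Operates on the n x 2p matrix of Procrustes coordinates produced by
superimposition (or on PC scores derived from it):

* PCA with variance-threshold retention (99% of total shape variance by
  default) to reduce dimensionality before discriminant analysis;
* factorial permutation shape-ANOVA (sequential sums of squares with
  residual-randomization permutation, the standard Procrustes-ANOVA design);
* classical MANOVA via Pillai's trace with its approximate F;
* canonical variate analysis (CVA) normalizing within-group variance;
* twofold cross-validated classification (CCV) with Mahalanobis assignment;
* predictive assignment of unknown specimens;
* shape reconstruction along ordination/discriminant axes by multivariate
  regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

log = logging.getLogger(__name__)


@dataclass
class ShapeMatrix:
    """Procrustes coordinates with per-specimen grouping factors."""

    X: np.ndarray                 # (n, 2p)
    ids: list[str]
    factors: pd.DataFrame         # per-row factors (e.g. taxon, tooth)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("shape matrix contains missing values")
        if len(self.ids) != self.X.shape[0] or len(self.factors) != self.X.shape[0]:
            raise ValueError("ids/factors length must match rows of X")


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaModel:
    mean: np.ndarray          # (d,)
    eigenvalues: np.ndarray   # non-increasing, >= 0
    vectors: np.ndarray       # (d, r) orthonormal columns
    scores: np.ndarray        # (n, r)
    retained_m: int
    variance_threshold: float

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained_m]

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def project(self, X: np.ndarray, retained_only: bool = True) -> np.ndarray:
        """Project new observations onto the principal axes."""
        V = self.vectors[:, : self.retained_m] if retained_only else self.vectors
        return (np.atleast_2d(X) - self.mean) @ V


def pca(X: np.ndarray, threshold: float = 0.99) -> PcaModel:
    """Principal component analysis of the coordinate covariance.

    ``retained_m`` is the smallest number of components whose cumulative
    variance fraction reaches ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("zero total variance; PCA undefined")
    r = int((s > s[0] * 1e-12).sum()) if s.size else 0
    eigenvalues = eigenvalues[:r]
    vectors = Vt[:r].T
    scores = U[:, :r] * s[:r]
    cum = np.cumsum(eigenvalues) / total
    retained_m = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    retained_m = min(retained_m, r)
    return PcaModel(
        mean=mean,
        eigenvalues=eigenvalues,
        vectors=vectors,
        scores=scores,
        retained_m=retained_m,
        variance_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Factorial permutation shape-ANOVA (residual randomization)

@dataclass
class AnovaTable:
    """Sequential shape-ANOVA table with permutation p-values."""

    table: pd.DataFrame     # index: terms, Residuals, Total
    n_perm: int
    seed: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def _design(levels: pd.Series) -> np.ndarray:
    return pd.get_dummies(levels, drop_first=True).to_numpy(dtype=float)


def _hat(Xd: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(Xd)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def factorial_shape_anova(
    X: np.ndarray,
    factor_a,
    factor_b=None,
    n_perm: int = 999,
    seed: int = 0,
    term_names: tuple[str, ...] | None = None,
) -> AnovaTable:
    """Sequential (type-I) shape ANOVA with residual-randomization p-values.

    With two factors the multivariate linear model on the coordinates is
    fitted with terms A, B, A:B in that order (pass the factors in the
    desired order); with ``factor_b=None`` a one-factor model is fitted,
    whose F for a two-level factor is Goodall's F on Procrustes distances.
    For each term, F = MS_term / MS_residual; the null distribution is
    obtained by randomizing the residuals of the reduced model (all earlier
    terms), the standard residual-randomization permutation procedure for
    Procrustes data.  Z is the standardized position of the observed F in
    its permutation distribution, and the p-value counts the observed
    statistic among the permutations.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    fa = pd.Series(list(factor_a)).astype(str)
    if fa.nunique() < 2:
        raise ValueError("factor A must have at least two levels")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")

    ones = np.ones((n, 1))
    A = _design(fa)
    if factor_b is not None:
        fb = pd.Series(list(factor_b)).astype(str)
        if fb.nunique() < 2:
            raise ValueError("factor B must have at least two levels")
        B = _design(fb)
        AB = np.einsum("ni,nj->nij", A, B).reshape(n, -1)
        cells = (fa + "\x00" + fb).nunique()
        if cells < fa.nunique() * fb.nunique():
            log.warning(
                "empty cells in the A x B design; sequential SS still computed"
            )
        designs = [
            ones,
            np.hstack([ones, A]),
            np.hstack([ones, A, B]),
            np.hstack([ones, A, B, AB]),
        ]
        names = term_names or ("A", "B", "A:B")
    else:
        designs = [ones, np.hstack([ones, A])]
        names = term_names or ("A",)
    n_terms = len(designs) - 1
    if len(names) != n_terms:
        raise ValueError("term_names length does not match the model terms")

    hats = [_hat(d) for d in designs]
    ranks = [int(round(np.trace(h))) for h in hats]
    df_terms = [ranks[k] - ranks[k - 1] for k in range(1, n_terms + 1)]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    diffs = [hats[k] - hats[k - 1] for k in range(1, n_terms + 1)]
    R_full = np.eye(n) - hats[-1]

    ss_obs = np.array([float(np.sum((D @ X) ** 2)) for D in diffs])
    ss_res = float(np.sum((R_full @ X) ** 2))
    ms_res = ss_res / df_res
    ss_total = float(np.sum((X - X.mean(axis=0)) ** 2))
    degenerate = ms_res <= 0 or ss_total <= 0
    f_obs = (
        np.full(n_terms, np.nan)
        if degenerate
        else (ss_obs / df_terms) / ms_res
    )

    p_vals, z_vals = [np.nan] * n_terms, [np.nan] * n_terms
    if not degenerate:
        rng = np.random.default_rng(seed)
        f_perm = np.empty((n_perm, n_terms))
        fitted_red = [hats[k] @ X for k in range(n_terms)]
        resid_red = [X - f for f in fitted_red]
        for b_ in range(n_perm):
            perm = rng.permutation(n)
            for k in range(n_terms):
                Yp = fitted_red[k] + resid_red[k][perm]
                ss_t = float(np.sum((diffs[k] @ Yp) ** 2))
                ss_r = float(np.sum((R_full @ Yp) ** 2))
                f_perm[b_, k] = (ss_t / df_terms[k]) / (ss_r / df_res)
        p_vals, z_vals = [], []
        for k in range(n_terms):
            dist = f_perm[:, k]
            p_vals.append((1 + np.sum(dist >= f_obs[k])) / (n_perm + 1))
            sd = dist.std(ddof=1)
            z_vals.append((f_obs[k] - dist.mean()) / sd if sd > 0 else np.nan)

    def _rsq(ss: float) -> float:
        return ss / ss_total if ss_total > 0 else np.nan

    rows = []
    for k, name in enumerate(names):
        rows.append(
            dict(
                term=name, df=df_terms[k], SS=ss_obs[k],
                MS=ss_obs[k] / df_terms[k] if df_terms[k] else np.nan,
                Rsq=_rsq(ss_obs[k]), F=f_obs[k], Z=z_vals[k], p=p_vals[k],
            )
        )
    rows.append(dict(term="Residuals", df=df_res, SS=ss_res, MS=ms_res,
                     Rsq=_rsq(ss_res), F=np.nan, Z=np.nan, p=np.nan))
    rows.append(dict(term="Total", df=n - 1, SS=ss_total, MS=np.nan,
                     Rsq=1.0 if ss_total > 0 else np.nan, F=np.nan, Z=np.nan, p=np.nan))
    table = pd.DataFrame(rows).set_index("term")
    return AnovaTable(table=table, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Classical MANOVA (Pillai's trace)

@dataclass
class ManovaResult:
    pillai: float
    approx_f: float
    num_df: int
    den_df: int
    p: float


def _sscp(scores: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-group SSCP matrices."""
    grand = scores.mean(axis=0)
    levels = np.unique(groups)
    m = scores.shape[1]
    B = np.zeros((m, m))
    W = np.zeros((m, m))
    for g in levels:
        sub = scores[groups == g]
        mg = sub.mean(axis=0)
        d = (mg - grand)[:, None]
        B += len(sub) * (d @ d.T)
        r = sub - mg
        W += r.T @ r
    return B, W


def manova_pillai(scores: np.ndarray, groups) -> ManovaResult:
    """One-way MANOVA using Pillai's trace with the standard approximate F."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    n, m = scores.shape
    g = len(np.unique(groups))
    if m >= n - g:
        raise ValueError(
            "within-group covariance is singular; retain fewer PCs "
            f"(m={m} must be < n - groups = {n - g})"
        )
    B, W = _sscp(scores, groups)
    try:
        V = float(np.trace(B @ np.linalg.inv(B + W)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular total covariance; retain fewer PCs") from exc
    q = g - 1                       # hypothesis df
    v = n - g                       # error df
    s = min(m, q)
    M = (abs(m - q) - 1) / 2.0
    N = (v - m - 1) / 2.0
    num_df = int(s * (2 * M + s + 1))
    den_df = int(s * (2 * N + s + 1))
    approx_f = (2 * N + s + 1) / (2 * M + s + 1) * V / (s - V)
    p = float(scipy.stats.f.sf(approx_f, num_df, den_df))
    return ManovaResult(pillai=V, approx_f=approx_f, num_df=num_df,
                        den_df=den_df, p=p)


# ---------------------------------------------------------------------------
# Canonical variate analysis

@dataclass
class CvaModel:
    """Discriminant axes normalizing the pooled within-group variance."""

    axes: np.ndarray          # (m, s): X_centered @ axes gives canonical variates
    eigenvalues: np.ndarray   # (s,) between/within variance ratios, descending
    groups: list[str]
    group_means: np.ndarray   # (g, s) in canonical space
    grand_mean: np.ndarray    # (m,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.grand_mean) @ self.axes

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        """(n, g) squared Mahalanobis distances to each group centroid.

        The pooled within-group covariance is the identity in canonical
        space, so these are squared Euclidean distances there.
        """
        Z = self.transform(X)
        diff = Z[:, None, :] - self.group_means[None, :, :]
        return np.sum(diff**2, axis=2)


def cva(scores: np.ndarray, groups, allow_singletons: bool = False) -> CvaModel:
    """Canonical variate analysis on (retained-PC) scores.

    Solves the generalized eigenproblem between x within; axes are scaled so
    each canonical variate has unit pooled within-group variance.
    ``allow_singletons`` admits groups with a single member (they contribute
    a centroid but no within-group variance), as needed when fitting on the
    training half of a twofold split of a two-specimen group.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    levels = [str(l) for l in np.unique(groups)]
    counts = {l: int((groups == l).sum()) for l in levels}
    for l, c in counts.items():
        if c < 2 and not allow_singletons:
            raise ValueError(f"group {l!r} has fewer than 2 members")
    n, m = scores.shape
    g = len(levels)
    B, W = _sscp(scores, groups)
    Bm = B / (g - 1)
    Wm = W / (n - g)
    try:
        evals, evecs = scipy.linalg.eigh(Bm, Wm)
        if not np.all(np.isfinite(evals)):
            raise np.linalg.LinAlgError("non-finite eigenvalues")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(
            "pooled within-group covariance is singular; retain fewer PCs"
        ) from exc
    order = np.argsort(evals)[::-1]
    s = min(g - 1, m)
    evals = np.maximum(evals[order][:s], 0.0)
    axes = evecs[:, order][:, :s]
    # eigh(B, W) normalizes v' W v = 1 with W = pooled covariance: unit
    # within-group variance of each canonical variate already holds.
    grand = scores.mean(axis=0)
    gm = np.vstack([(scores[groups == l].mean(axis=0) - grand) @ axes for l in levels])
    return CvaModel(axes=axes, eigenvalues=evals, groups=levels,
                    group_means=gm, grand_mean=grand)


# ---------------------------------------------------------------------------
# Twofold cross-validated classification (CCV)

@dataclass
class ClassificationReport:
    groups: list[str]
    ids: list[str]
    true_groups: np.ndarray
    assignment_rates: np.ndarray   # (n, g) mean assignment rate per specimen
    ccv: float                     # per-round mean correct percentage
    ccv_modal: float               # % specimens whose modal assignment is correct
    ccv_per_group: dict[str, float]
    confusion: pd.DataFrame        # true x assigned rates
    rounds: int
    seed: int


def crossvalidated_classification(
    scores: np.ndarray,
    groups,
    rounds: int = 1000,
    seed: int = 0,
    ids: list[str] | None = None,
) -> ClassificationReport:
    """Twofold cross-validated CVA classification over many random splits.

    Each round splits every group at random into training and testing halves
    (alternating ceil/floor training sizes so odd groups are covered both
    ways), fits the CVA on the training rows, and assigns each testing row to
    the group with minimum Mahalanobis distance in canonical space (equal
    priors; ties broken toward the lowest group index).  CCV is the mean
    per-round percentage of correct assignments; the modal-assignment
    percentage is reported alongside.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    n = scores.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    levels = [str(l) for l in np.unique(groups)]
    gidx = {l: np.flatnonzero(groups == l) for l in levels}
    for l, idx in gidx.items():
        if len(idx) < 2:
            raise ValueError(f"group {l!r} has fewer than 2 members")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    g = len(levels)
    level_pos = {l: k for k, l in enumerate(levels)}
    true_pos = np.array([level_pos[t] for t in groups])

    rng = np.random.default_rng(seed)
    assign_counts = np.zeros((n, g))
    tested_counts = np.zeros(n)
    round_acc = np.empty(rounds)
    redraws = 0
    r = 0
    while r < rounds:
        train_idx, test_idx = [], []
        for l in levels:
            idx = gidx[l]
            perm = rng.permutation(idx)
            parity = (r + redraws) % 2   # redraws flip parity so a split
            ntr = (                      # untrainable at one parity recovers
                math.ceil(len(idx) / 2) if parity == 0 else max(1, len(idx) // 2)
            )
            train_idx.extend(perm[:ntr])
            test_idx.extend(perm[ntr:])
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        if len(test_idx) == 0:
            raise ValueError("no testing rows; groups too small for twofold CV")
        try:
            model = cva(scores[train_idx], groups[train_idx], allow_singletons=True)
        except ValueError:
            redraws += 1
            if redraws >= 5 and redraws > (r + redraws) / 2:
                raise ValueError(
                    "more than half of the cross-validation splits were "
                    "untrainable (singular within-group covariance); retain "
                    "fewer PCs"
                )
            log.warning("untrainable split redrawn (round %d)", r)
            continue
        d2 = model.mahalanobis_sq(scores[test_idx])
        assigned = np.argmin(d2, axis=1)     # argmin takes lowest index on ties
        model_pos = np.array([level_pos[l] for l in model.groups])
        assigned_global = model_pos[assigned]
        assign_counts[test_idx, assigned_global] += 1
        tested_counts[test_idx] += 1
        round_acc[r] = float(np.mean(assigned_global == true_pos[test_idx]))
        r += 1

    tested = np.maximum(tested_counts, 1)[:, None]
    rates = assign_counts / tested
    modal = rates.argmax(axis=1)
    ccv_modal = 100.0 * float(np.mean(modal == true_pos))
    ccv = 100.0 * float(round_acc.mean())
    per_group = {}
    confusion = np.zeros((g, g))
    for l in levels:
        k = level_pos[l]
        rows = gidx[l]
        confusion[k] = assign_counts[rows].sum(axis=0) / max(
            tested_counts[rows].sum(), 1
        )
        per_group[l] = 100.0 * confusion[k, k]
    return ClassificationReport(
        groups=levels,
        ids=list(ids),
        true_groups=groups,
        assignment_rates=rates,
        ccv=ccv,
        ccv_modal=ccv_modal,
        ccv_per_group=per_group,
        confusion=pd.DataFrame(confusion, index=levels, columns=levels),
        rounds=rounds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Predictive assignment of unknowns

@dataclass
class Prediction:
    group: str
    posteriors: dict[str, float]
    mahalanobis_sq: dict[str, float]


def predict_unknown(
    model: CvaModel, pca_model: PcaModel, unknown_scores: np.ndarray
) -> list[Prediction]:
    """Assign unknown specimens to groups by Mahalanobis distance.

    ``unknown_scores`` are the unknowns projected onto the training PCA's
    retained axes (use :func:`enamelgmm.procrustes.align_to_consensus` and
    :meth:`PcaModel.project` to get there from raw configurations).
    Posterior probabilities are proportional to exp(-D^2/2) with equal
    priors.
    """
    Z = np.atleast_2d(np.asarray(unknown_scores, dtype=float))
    if Z.shape[1] != model.axes.shape[0]:
        raise ValueError(
            f"unknowns have {Z.shape[1]} variables; model expects "
            f"{model.axes.shape[0]} retained PCs"
        )
    d2 = model.mahalanobis_sq(Z)
    out = []
    for row in d2:
        logp = -row / 2.0
        post = np.exp(logp - logp.max())
        post = post / post.sum()
        k = int(np.argmax(post))
        out.append(
            Prediction(
                group=model.groups[k],
                posteriors=dict(zip(model.groups, post.tolist())),
                mahalanobis_sq=dict(zip(model.groups, row.tolist())),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Shape reconstruction along axes

def shape_along_scores(coords: np.ndarray, axis_scores: np.ndarray, score: float) -> np.ndarray:
    """Shape predicted at a given score by multivariate regression.

    Regresses every Procrustes coordinate on the axis scores and evaluates
    the fitted model at ``score``; at 0 this returns the consensus (mean).
    Returns a (p, 2) configuration.
    """
    coords = np.asarray(coords, dtype=float)
    s = np.asarray(axis_scores, dtype=float)
    sc = s - s.mean()
    var = float(sc @ sc)
    if var <= 0:
        raise ValueError("axis scores have zero variance")
    slope = (coords - coords.mean(axis=0)).T @ sc / var
    flat = coords.mean(axis=0) + score * slope
    return flat.reshape(-1, 2)


def shape_along_axis(pca_model: PcaModel, axis: int, score: float) -> np.ndarray:
    """Shape at ``score`` along a principal axis (regression form).

    For PCA the coordinate-on-score regression vector equals the eigenvector,
    so this is mean + score * eigenvector, reshaped to (p, 2).
    """
    if not 0 <= axis < pca_model.vectors.shape[1]:
        raise IndexError(f"axis {axis} out of range")
    flat = pca_model.mean + score * pca_model.vectors[:, axis]
    return flat.reshape(-1, 2)
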