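"""Statistical layer: subject embeddings, the PLS motor-function index,
correlation panels, the age x cohort mixed model, and baseline comparisons.

The motor-function index is the first X-side weight vector of a two-block
canonical-mode PLS linking wearable shape features (VPC1/VPC2 scores from arm
curl and knock) to clinical measures (age, muscle echogenicity, normalized
elbow torque, Brooke score).  Its sampling variability is quantified by a
subject-level bootstrap: each replicate resamples subjects with replacement
into a training set, fits PLS there, and records the Pearson correlation of
the first score pair on the held-out subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSCanonical
from sklearn.decomposition import NMF, PCA
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .curves import SrvfCurve, Trajectory
from .pca import ShapePcaModel, fit_shape_pca, project
from .registration import separate_phase_amplitude

__all__ = [
    "IndexModel",
    "repeated_shape_pca",
    "fit_pls",
    "bootstrap_pls",
    "pearson_panel",
    "age_mixed_model",
    "baseline_comparison",
    "DEFAULT_Y_VARS",
]

logger = logging.getLogger(__name__)

DEFAULT_Y_VARS = ("age", "avg_echo", "net", "brooke")


# ---------------------------------------------------------------------------
# repeated random-visit shape PCA
# ---------------------------------------------------------------------------

def _group_by_activity(trajectories: list[Trajectory]) -> dict[str, dict[str, dict[int, Trajectory]]]:
    out: dict[str, dict[str, dict[int, Trajectory]]] = {}
    for tr in trajectories:
        out.setdefault(tr.activity, {}).setdefault(tr.subject_id, {})[tr.visit] = tr
    return out


def repeated_shape_pca(
    trajectories: list[Trajectory],
    n_runs: int = 100,
    n_retained: int = 2,
    seed: int = 0,
    refit_alignment: bool = True,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> pd.DataFrame:
    """Subject embedding from repeated random-visit shape PCA.

    Per run one visit is sampled uniformly per subject, shape PCA is fitted
    per activity, components are sign-aligned to the first run (a component
    is flipped when its inner product with the first run's matching component
    is negative), and subjects are projected.  The embedding is the
    across-run mean score per subject; per-feature across-run standard
    deviations are reported alongside.

    With ``refit_alignment`` the phase-amplitude separation is redone on each
    run's curves; otherwise one global separation (all curves pooled) is
    reused and only the PCA is refitted per run, which is much faster.
    """
    rng = np.random.default_rng(seed)
    by_act = _group_by_activity(trajectories)
    subjects = sorted({tr.subject_id for tr in trajectories})

    cache: dict[str, dict[tuple[str, int], SrvfCurve]] = {}
    if not refit_alignment:
        for act, subj_map in sorted(by_act.items()):
            curves = [subj_map[s][v] for s in sorted(subj_map) for v in sorted(subj_map[s])]
            sep = separate_phase_amplitude(curves, tol=tol, max_iter=max_iter)
            cache[act] = {
                (c.subject_id, c.visit): q for c, q in zip(curves, sep.aligned_srvfs)
            }

    run_scores: dict[tuple[str, str], list[float]] = {}
    ref_models: dict[str, ShapePcaModel] = {}
    feature_names: list[str] = []

    for run in range(n_runs):
        for act, subj_map in sorted(by_act.items()):
            chosen: list[tuple[str, int]] = []
            for s in sorted(subj_map):
                visits = sorted(subj_map[s])
                if not visits:
                    logger.warning("subject %s has no visits for %s; excluded", s, act)
                    continue
                chosen.append((s, int(rng.choice(visits))))
            if refit_alignment:
                curves = [subj_map[s][v] for s, v in chosen]
                sep = separate_phase_amplitude(curves, tol=tol, max_iter=max_iter)
                aligned = sep.aligned_srvfs
            else:
                aligned = [cache[act][key] for key in chosen]
            model = fit_shape_pca(aligned, n_retained=n_retained, activity=act)
            if run == 0:
                ref_models[act] = model
            else:
                ref = ref_models[act]
                for k in range(model.n_retained):
                    if float(np.dot(model.components[k], ref.components[k])) < 0:
                        model.components[k] = -model.components[k]
            for (s, _v), q in zip(chosen, aligned):
                scores = project(q, model)
                for k in range(model.n_retained):
                    name = f"VPC{k + 1}_{act}"
                    run_scores.setdefault((s, name), []).append(float(scores[k]))
                    if run == 0 and name not in feature_names:
                        feature_names.append(name)

    rows = []
    for s in subjects:
        row: dict[str, float | str | int] = {"subject_id": s}
        for f in feature_names:
            if (s, f) in run_scores:
                vals = np.asarray(run_scores[(s, f)])
                row[f] = float(vals.mean())
                row[f"sd_{f}"] = float(vals.std())
        row["n_runs"] = n_runs
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PLS canonical index
# ---------------------------------------------------------------------------

@dataclass
class IndexModel:
    """Point fit and (optionally) bootstrap distributions of the PLS index."""

    x_weights: np.ndarray                 # (p, K), unit-norm columns
    y_weights: np.ndarray                 # (q, K)
    feature_names: list[str]
    y_names: list[str]
    train_correlations: np.ndarray        # (K,), on the training data
    n_components: int
    corr_distribution: np.ndarray | None = None   # (n_eff, K) held-out r
    coef_distribution: np.ndarray | None = None   # (n_eff, p) first-comp x-weights
    medians: np.ndarray | None = None
    intervals: dict[str, np.ndarray] = dc_field(default_factory=dict)
    n_boot: int = 0
    n_skipped: int = 0
    train_frac: float = 0.7
    seed: int | None = None

    @property
    def index_weights(self) -> np.ndarray:
        """First-component X weights: the motor-function index."""
        return self.x_weights[:, 0]

    def summary(self) -> dict:
        out = {
            "feature_names": self.feature_names,
            "y_names": self.y_names,
            "index_weights": self.index_weights.tolist(),
            "train_correlations": self.train_correlations.tolist(),
            "n_components": self.n_components,
        }
        if self.corr_distribution is not None:
            out.update(
                {
                    "median_correlations": self.medians.tolist(),
                    "intervals": {k: v.tolist() for k, v in self.intervals.items()},
                    "n_boot": self.n_boot,
                    "n_skipped": self.n_skipped,
                    "train_frac": self.train_frac,
                    "seed": self.seed,
                }
            )
        return out


def _as_matrix(X, names_hint: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"{names_hint}{i + 1}" for i in range(X.shape[1])]


def _drop_constant(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep = X.std(axis=0) > 1e-12
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant columns {dropped}", RuntimeWarning)
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def fit_pls(X, Y, n_components: int = 3) -> IndexModel:
    """Two-block canonical-mode PLS on standardized blocks (point fit).

    The first component's X-side weights define the motor-function index;
    training canonical correlations are the Pearson correlations of the
    paired latent scores.
    """
    X, x_names = _as_matrix(X, "x")
    Y, y_names = _as_matrix(Y, "y")
    mask = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    if mask.sum() < len(mask):
        logger.info("fit_pls: dropping %d incomplete cases", int(len(mask) - mask.sum()))
    X, Y = X[mask], Y[mask]
    if X.shape[0] < 5:
        raise ValueError("fit_pls needs at least 5 complete cases")
    X, x_names = _drop_constant(X, x_names)
    Y, y_names = _drop_constant(Y, y_names)
    max_k = min(X.shape[1], Y.shape[1], X.shape[0] - 1)
    if n_components > max_k:
        warnings.warn(f"n_components truncated to {max_k}", RuntimeWarning)
        n_components = max_k
    pls = PLSCanonical(n_components=n_components, scale=True, algorithm="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, Y)
    xs, ys = pls.transform(X, Y)
    corrs = np.array(
        [stats.pearsonr(xs[:, k], ys[:, k]).statistic for k in range(n_components)]
    )
    return IndexModel(
        x_weights=pls.x_weights_.copy(),
        y_weights=pls.y_weights_.copy(),
        feature_names=x_names,
        y_names=y_names,
        train_correlations=corrs,
        n_components=n_components,
    )


def bootstrap_pls(
    X,
    Y,
    n_boot: int = 10000,
    train_frac: float = 0.7,
    n_components: int = 3,
    seed: int = 0,
) -> IndexModel:
    """Subject-level bootstrap of the PLS index.

    Each replicate resamples ``train_frac`` of the subjects with replacement
    into a training set; subjects never drawn form the hold-out set.  PLS is
    fitted on the training set and the Pearson correlation of each held-out
    score pair is recorded.  Replicates with a degenerate hold-out (< 3
    subjects, or a zero-variance score) are skipped and counted.  Replicate
    weight vectors are sign-aligned to the full-data point fit so coefficient
    distributions are comparable.  Percentile intervals are reported at both
    2.5-97.5 and 5-95.
    """
    Xm, x_names = _as_matrix(X, "x")
    Ym, y_names = _as_matrix(Y, "y")
    mask = np.isfinite(Xm).all(axis=1) & np.isfinite(Ym).all(axis=1)
    Xm, Ym = Xm[mask], Ym[mask]
    point = fit_pls(pd.DataFrame(Xm, columns=x_names),
                    pd.DataFrame(Ym, columns=y_names), n_components=n_components)
    n_components = point.n_components
    n = Xm.shape[0]
    n_train = max(int(round(train_frac * n)), 2)
    rng = np.random.default_rng(seed)

    corr_rows, coef_rows = [], []
    n_skipped = 0
    all_idx = np.arange(n)
    for _ in range(n_boot):
        train = rng.choice(n, size=n_train, replace=True)
        hold = np.setdiff1d(all_idx, np.unique(train))
        if hold.size < 3:
            n_skipped += 1
            continue
        Xt, Yt = Xm[train], Ym[train]
        if (Xt.std(axis=0) <= 1e-12).any() or (Yt.std(axis=0) <= 1e-12).any():
            n_skipped += 1
            continue
        pls = PLSCanonical(n_components=n_components, scale=True, algorithm="svd")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(Xt, Yt)
                xs, ys = pls.transform(Xm[hold], Ym[hold])
        except Exception:
            n_skipped += 1
            continue
        if (xs.std(axis=0) <= 1e-12).any() or (ys.std(axis=0) <= 1e-12).any():
            n_skipped += 1
            continue
        r = [stats.pearsonr(xs[:, k], ys[:, k]).statistic for k in range(n_components)]
        corr_rows.append(r)
        w = pls.x_weights_[:, 0].copy()
        if float(np.dot(w, point.x_weights[:, 0])) < 0:
            w = -w
        coef_rows.append(w)

    corr = np.array(corr_rows) if corr_rows else np.empty((0, n_components))
    coefs = np.array(coef_rows) if coef_rows else np.empty((0, Xm.shape[1]))
    medians = np.median(corr, axis=0) if corr.size else np.full(n_components, np.nan)
    intervals = {}
    if corr.size:
        intervals["5-95"] = np.percentile(corr, [5, 95], axis=0)
        intervals["2.5-97.5"] = np.percentile(corr, [2.5, 97.5], axis=0)
    return IndexModel(
        x_weights=point.x_weights,
        y_weights=point.y_weights,
        feature_names=point.feature_names,
        y_names=point.y_names,
        train_correlations=point.train_correlations,
        n_components=n_components,
        corr_distribution=corr,
        coef_distribution=coefs,
        medians=medians,
        intervals=intervals,
        n_boot=n_boot,
        n_skipped=n_skipped,
        train_frac=train_frac,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# correlation panel and mixed model
# ---------------------------------------------------------------------------

def pearson_panel(
    embedding: pd.DataFrame,
    clinical: pd.DataFrame,
    features: list[str] | None = None,
    clinical_vars: tuple[str, ...] = DEFAULT_Y_VARS,
) -> pd.DataFrame:
    """Per-cohort Pearson correlations of VPC features with clinical measures.

    Complete cases per pair; the Brooke score is omitted for the Healthy
    cohort (not collected there); zero-variance pairs are reported as NaN and
    flagged undefined rather than 0.
    """
    if features is None:
        features = [c for c in embedding.columns
                    if c.startswith("VPC") and not c.startswith("sd_")]
    merged = embedding.merge(clinical, on="subject_id", how="inner")
    rows = []
    for cohort, grp in merged.groupby("cohort"):
        for f in features:
            for cv in clinical_vars:
                if cv == "brooke" and cohort == "Healthy":
                    continue
                sub = grp[[f, cv]].dropna()
                n = len(sub)
                r, undefined = np.nan, False
                if n < 3:
                    undefined = True
                elif sub[f].std() <= 1e-12 or sub[cv].std() <= 1e-12:
                    undefined = True
                else:
                    r = float(stats.pearsonr(sub[f], sub[cv]).statistic)
                rows.append(
                    {"cohort": cohort, "feature": f, "clinical": cv,
                     "n": n, "r": r, "undefined": undefined}
                )
    return pd.DataFrame(rows)


def age_mixed_model(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.01,
    score_col: str = "score",
    reference: str = "Healthy",
) -> pd.DataFrame:
    """Random-intercept mixed model of a per-visit VPC score on age x cohort.

    Fixed effects are age, cohort, and their interaction (treatment coding
    against ``reference``); a random intercept absorbs repeated visits per
    subject.  Two-sided Wald p-values are Benjamini-Hochberg adjusted across
    the reported fixed effects and flagged significant at ``alpha``.  A
    singular or non-converged fit is reported through the ``note`` attribute,
    never raised.
    """
    data = scores.merge(clinical[["subject_id", "cohort", "age"]], on="subject_id")
    data = data.dropna(subset=[score_col, "age", "cohort"])
    if data["cohort"].nunique() < 2:
        raise ValueError("age_mixed_model needs at least 2 cohorts")
    formula = f"{score_col} ~ age * C(cohort, Treatment('{reference}'))"
    note = ""
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data, groups=data["subject_id"])
        result = model.fit(reml=True)
        for w in wlist:
            if "singular" in str(w.message).lower() or "converge" in str(w.message).lower():
                note = str(w.message)
    fe = result.fe_params
    terms = list(fe.index)
    table = pd.DataFrame(
        {
            "term": terms,
            "coef": fe.values,
            "se": result.bse_fe.values,
            "z": result.fe_params.values / result.bse_fe.values,
            "p": result.pvalues[terms].values,
        }
    )
    ok = np.isfinite(table["p"].to_numpy())
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok] = multipletests(table["p"].to_numpy()[ok], method="fdr_bh")[1]
    table["p_bh"] = adj
    table["significant"] = table["p_bh"] < alpha
    table["ci_low"] = table["coef"] - 1.959964 * table["se"]
    table["ci_high"] = table["coef"] + 1.959964 * table["se"]
    table.attrs["note"] = note
    table.attrs["alpha"] = alpha
    table.attrs["converged"] = bool(getattr(result, "converged", True))
    return table


# ---------------------------------------------------------------------------
# baseline decomposition comparison
# ---------------------------------------------------------------------------

def _visit1_matrix(trajectories: list[Trajectory], activity: str) -> tuple[np.ndarray, list[str]]:
    by_act = _group_by_activity(trajectories)[activity]
    subjects = sorted(by_act)
    rows = [by_act[s][min(by_act[s])].values for s in subjects]
    return np.stack(rows), subjects


def baseline_comparison(
    trajectories: list[Trajectory],
    clinical: pd.DataFrame,
    n_boot: int = 1000,
    train_frac: float = 0.7,
    n_components: int = 3,
    seed: int = 0,
    n_retained: int = 2,
    y_vars: tuple[str, ...] = DEFAULT_Y_VARS,
    cohorts: tuple[str, ...] = ("DMD", "SMA"),
) -> pd.DataFrame:
    """Bootstrap-PLS comparison of shape PCA against unaligned baselines.

    Subject features (one curve per subject per activity, first visit) are
    extracted three ways — elastic shape PCA on aligned SRVFs, functional PCA
    on the unaligned curves, and NMF on nonnegatively shifted unaligned
    curves — then pushed through the identical bootstrap harness.  Emits the
    median and percentile interval of the held-out canonical correlation per
    component per method.
    """
    activities = sorted({t.activity for t in trajectories})
    features: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)
    nmf_seed = int(rng.integers(0, 2**31 - 1))
    boot_seed = int(rng.integers(0, 2**31 - 1))

    for method in ("shape_pca_aligned", "fpca_unaligned", "nmf_unaligned"):
        cols: dict[str, np.ndarray] = {}
        subjects_ref: list[str] | None = None
        for act in activities:
            M, subjects = _visit1_matrix(trajectories, act)
            subjects_ref = subjects
            if method == "shape_pca_aligned":
                curves = [Trajectory(trajectories[0].grid, row, subject_id=s, activity=act)
                          for row, s in zip(M, subjects)]
                sep = separate_phase_amplitude(curves)
                model = fit_shape_pca(sep.aligned_srvfs, n_retained=n_retained, activity=act)
                S = np.stack([project(q, model) for q in sep.aligned_srvfs])
            elif method == "fpca_unaligned":
                S = PCA(n_components=n_retained).fit_transform(M)
            else:
                shifted = M - M.min()
                nmf = NMF(n_components=n_retained, init="nndsvda",
                          random_state=nmf_seed, max_iter=1000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    S = nmf.fit_transform(shifted)
            for k in range(n_retained):
                cols[f"C{k + 1}_{act}"] = S[:, k]
        feat = pd.DataFrame(cols)
        feat.insert(0, "subject_id", subjects_ref)
        features[method] = feat

    clin = clinical[clinical["cohort"].isin(cohorts)]
    rows = []
    for method, feat in features.items():
        merged = feat.merge(clin, on="subject_id", how="inner")
        merged = merged.dropna(subset=list(y_vars))
        Xcols = [c for c in feat.columns if c != "subject_id"]
        model = bootstrap_pls(
            merged[Xcols], merged[list(y_vars)],
            n_boot=n_boot, train_frac=train_frac,
            n_components=n_components, seed=boot_seed,
        )
        for k in range(model.n_components):
            rows.append(
                {
                    "method": method,
                    "component": k + 1,
                    "median": model.medians[k],
                    "p5": model.intervals["5-95"][0, k],
                    "p95": model.intervals["5-95"][1, k],
                    "p2_5": model.intervals["2.5-97.5"][0, k],
                    "p97_5": model.intervals["2.5-97.5"][1, k],
                    "n_skipped": model.n_skipped,
                }
            )
    return pd.DataFrame(rows)
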