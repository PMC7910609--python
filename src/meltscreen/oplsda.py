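"""Orthogonal partial least squares discriminant analysis (OPLS-DA) on the
protein-Tm matrix, with variable-importance-in-projection (VIP) scoring.

Observations are samples (rows), variables are proteins (columns), and the
response is the binary class membership (+1 / −1).  The NIPALS-style OPLS
algorithm first removes ``n_ortho`` components of X-variation orthogonal to
the class response, then extracts a single predictive component; proteins
with large predictive loadings drive the class separation.  VIP is
normalized so that the mean squared VIP over included proteins is 1 —
proteins with VIP > 1 contribute more than average to the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ModelError(RuntimeError):
    """Raised when the model cannot be fitted (rank deficiency, degeneracy)."""


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive + ``n_ortho`` orthogonal comps)."""

    proteins: pd.Index
    samples: list
    y: np.ndarray  # ±1 class vector
    x_mean: np.ndarray
    x_scale: np.ndarray
    w_pred: np.ndarray  # unit predictive weights (per protein)
    p_pred: np.ndarray  # predictive loadings
    t_pred: np.ndarray  # predictive scores (per sample)
    c_pred: float  # y-loading of the predictive component
    w_ortho: np.ndarray  # (n_ortho, K)
    p_ortho: np.ndarray  # (n_ortho, K)
    t_ortho: np.ndarray  # (n_ortho, N)
    r2x: float = float("nan")
    r2y: float = float("nan")
    q2: float = float("nan")
    ssx_components: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dropped_proteins: list = field(default_factory=list)
    reference_points: pd.DataFrame | None = None

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]

    def scores(self) -> pd.DataFrame:
        cols = {"t_pred": self.t_pred}
        for i in range(self.n_ortho):
            cols[f"t_ortho_{i + 1}"] = self.t_ortho[i]
        return pd.DataFrame(cols, index=pd.Index(self.samples, name="sample"))

    def loadings(self) -> pd.DataFrame:
        cols = {"w_pred": self.w_pred, "p_pred": self.p_pred}
        for i in range(self.n_ortho):
            cols[f"p_ortho_{i + 1}"] = self.p_ortho[i]
        return pd.DataFrame(cols, index=self.proteins)

    def transform(self, X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scale new rows, strip orthogonal variation, return (t_pred, t_ortho)."""
        X = (np.atleast_2d(X_raw) - self.x_mean) / self.x_scale
        t_os = []
        for i in range(self.n_ortho):
            t_o = X @ self.w_ortho[i]
            X = X - np.outer(t_o, self.p_ortho[i])
            t_os.append(t_o)
        t = X @ self.w_pred
        return t, np.array(t_os)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X_raw)
        return t * self.c_pred


def _sample_matrix(tm_table, sample_keys: list) -> pd.DataFrame:
    """Extract samples × proteins matrix (complete cases) from a TmTable."""
    cols = []
    for key in sample_keys:
        tup = (key.treatment, key.replicate) if hasattr(key, "treatment") else key
        if tup not in tm_table.tm.columns:
            raise ModelError(f"sample {tup} absent from Tm table")
        cols.append(tup)
    X = tm_table.tm[cols].dropna(axis=0)  # proteins × samples, complete cases
    return X.T  # samples × proteins


def fit_oplsda(
    tm_table_or_x,
    class_a: list,
    class_b: list,
    n_ortho: int = 1,
    *,
    scale: str = "uv",
) -> OplsModel:
    """Fit OPLS-DA contrasting ``class_a`` (+1) against ``class_b`` (−1).

    ``tm_table_or_x`` is either a :class:`~meltscreen.meltfit.TmTable`
    (``class_*`` are sample keys / (treatment, replicate) tuples) or a
    samples × proteins DataFrame (``class_*`` are row labels).  Columns are
    mean-centered and, with ``scale='uv'``, scaled to unit variance; zero-
    variance proteins are dropped with a warning.  Deterministic: single-y
    NIPALS needs no iteration.
    """
    if isinstance(tm_table_or_x, pd.DataFrame):
        Xa = tm_table_or_x.loc[list(class_a)]
        Xb = tm_table_or_x.loc[list(class_b)]
        Xdf = pd.concat([Xa, Xb]).dropna(axis=1)
    else:
        class_a = [
            (k.treatment, k.replicate) if hasattr(k, "treatment") else k
            for k in class_a
        ]
        class_b = [
            (k.treatment, k.replicate) if hasattr(k, "treatment") else k
            for k in class_b
        ]
        Xdf = _sample_matrix(tm_table_or_x, list(class_a) + list(class_b))
        Xdf = Xdf.loc[list(class_a) + list(class_b)]
    n_a, n_b = len(class_a), len(class_b)
    if n_a < 2 or n_b < 2:
        raise ModelError("need at least 2 samples per class")
    y = np.concatenate([np.ones(n_a), -np.ones(n_b)])

    sd = Xdf.std(axis=0, ddof=1)
    dropped = list(Xdf.columns[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance proteins")
        Xdf = Xdf.drop(columns=dropped)
    if Xdf.shape[1] == 0:
        raise ModelError("no usable proteins (all zero variance or missing)")

    X0 = Xdf.to_numpy(dtype=float)
    x_mean = X0.mean(axis=0)
    x_scale = (
        X0.std(axis=0, ddof=1) if scale == "uv" else np.ones(X0.shape[1])
    )
    X = (X0 - x_mean) / x_scale
    yc = y - y.mean()

    n_samples = X.shape[0]
    if n_ortho >= n_samples - 1:
        raise ModelError(
            f"n_ortho={n_ortho} too large for {n_samples} samples"
        )

    ssx_total = float(np.sum(X**2))
    ssy_total = float(np.sum(yc**2))

    def _w(Xc):
        w = Xc.T @ yc / (yc @ yc)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ModelError("degenerate model: X carries no class covariance")
        return w / norm

    Xd = X.copy()
    w_os, p_os, t_os, ssx_comp = [], [], [], []
    for _ in range(n_ortho):
        w = _w(Xd)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ModelError("no orthogonal variation left to remove")
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
        ssx_comp.append(float(np.sum(np.outer(t_o, p_o) ** 2)))

    w = _w(Xd)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    ssx_comp = [float(np.sum(np.outer(t, p) ** 2))] + ssx_comp

    r2x = sum(ssx_comp) / ssx_total if ssx_total > 0 else float("nan")
    y_hat = t * c
    r2y = 1.0 - float(np.sum((yc - y_hat) ** 2)) / ssy_total

    model = OplsModel(
        proteins=Xdf.columns,
        samples=list(Xdf.index),
        y=y,
        x_mean=x_mean,
        x_scale=x_scale,
        w_pred=w,
        p_pred=p,
        t_pred=t,
        c_pred=c,
        w_ortho=np.array(w_os) if w_os else np.zeros((0, X.shape[1])),
        p_ortho=np.array(p_os) if p_os else np.zeros((0, X.shape[1])),
        t_ortho=np.array(t_os) if t_os else np.zeros((0, n_samples)),
        r2x=r2x,
        r2y=r2y,
        ssx_components=np.array(ssx_comp),
        dropped_proteins=dropped,
    )
    model._x_train = Xdf
    model.q2 = _q2_loo(Xdf, class_a, class_b, n_ortho, scale)
    model.reference_points = _reference_points(model, n_a, n_b)
    return model


def _q2_loo(Xdf, class_a, class_b, n_ortho, scale) -> float:
    """Leave-one-out cross-validated Q² of the class prediction."""
    n = Xdf.shape[0]
    y = np.concatenate([np.ones(len(class_a)), -np.ones(len(class_b))])
    press, ss = 0.0, float(np.sum((y - y.mean()) ** 2))
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = Xdf.iloc[keep]
        ya = [s for s in Xdf.index[keep] if s in set(class_a)]
        yb = [s for s in Xdf.index[keep] if s in set(class_b)]
        if len(ya) < 1 or len(yb) < 1:
            return float("nan")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _fit_unchecked(sub, ya, yb, n_ortho, scale)
        except ModelError:
            return float("nan")
        pred = m.predict(Xdf.iloc[[i]][m.proteins].to_numpy())[0] + y[keep].mean()
        press += (y[i] - pred) ** 2
    return 1.0 - press / ss if ss > 0 else float("nan")


def _fit_unchecked(Xdf, class_a, class_b, n_ortho, scale) -> OplsModel:
    """Internal refit that tolerates a single sample per class (jackknife)."""
    n_a, n_b = len(class_a), len(class_b)
    Xsub = pd.concat([Xdf.loc[list(class_a)], Xdf.loc[list(class_b)]])
    sd = Xsub.std(axis=0, ddof=1)
    Xsub = Xsub.loc[:, (sd > 0)]
    y = np.concatenate([np.ones(n_a), -np.ones(n_b)])
    X0 = Xsub.to_numpy(dtype=float)
    x_mean = X0.mean(axis=0)
    x_scale = X0.std(axis=0, ddof=1) if scale == "uv" else np.ones(X0.shape[1])
    X = (X0 - x_mean) / x_scale
    yc = y - y.mean()

    def _w(Xc):
        w = Xc.T @ yc / (yc @ yc)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ModelError("degenerate")
        return w / norm

    Xd = X.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_ortho):
        w = _w(Xd)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    w = _w(Xd)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    return OplsModel(
        proteins=Xsub.columns,
        samples=list(Xsub.index),
        y=y,
        x_mean=x_mean,
        x_scale=x_scale,
        w_pred=w,
        p_pred=p,
        t_pred=t,
        c_pred=c,
        w_ortho=np.array(w_os) if w_os else np.zeros((0, X.shape[1])),
        p_ortho=np.array(p_os) if p_os else np.zeros((0, X.shape[1])),
        t_ortho=np.array(t_os) if t_os else np.zeros((0, X.shape[0])),
    )


def _reference_points(model: OplsModel, n_a: int, n_b: int) -> pd.DataFrame:
    """Loading-space coordinates of the class-indicator dummy variables.

    The reference point of a class is where an ideal variable perfectly
    correlated with that class (its autoscaled 0/1 indicator) would load:
    coordinate on each component axis = tᵀd̃ / tᵀt for the component scores t.
    Candidates specifically shifted toward a class cluster near its star.
    """
    n = n_a + n_b
    rows = {}
    for label, members in (("class_a", range(n_a)), ("class_b", range(n_a, n))):
        d = np.zeros(n)
        d[list(members)] = 1.0
        d = d - d.mean()
        sd = d.std(ddof=1)
        if sd > 0:
            d = d / sd
        coords = {"p_pred": float(model.t_pred @ d / (model.t_pred @ model.t_pred))}
        for i in range(model.n_ortho):
            t_o = model.t_ortho[i]
            coords[f"p_ortho_{i + 1}"] = float(t_o @ d / (t_o @ t_o))
        rows[label] = coords
    return pd.DataFrame(rows).T


def compute_vip(
    model: OplsModel,
    *,
    variant: str = "predictive",
    confidence: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """VIP per protein with optional jackknife confidence bounds.

    ``variant='predictive'`` scores contribution to the predictive component
    only: VIP_j = sqrt(K)·|w_j| with unit predictive weights (so ΣVIP² = K).
    ``variant='total'`` also credits orthogonal components, weighting each
    component's unit weight vector by its share of explained X-variance.
    Bounds at ``1−alpha`` come from leave-one-sample-out refits (small-sample
    jackknife — approximate by construction).
    """
    point = _vip_values(model, variant)
    out = pd.DataFrame({"vip": point}, index=model.proteins)
    if not confidence:
        out["vip_lo"] = np.nan
        out["vip_hi"] = np.nan
        return out

    n = len(model.samples)
    set_a = {s for s, yy in zip(model.samples, model.y) if yy > 0}
    X_raw = _training_matrix(model)
    reps = np.full((n, len(model.proteins)), np.nan)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        ya = [model.samples[j] for j in keep if model.samples[j] in set_a]
        yb = [model.samples[j] for j in keep if model.samples[j] not in set_a]
        if not ya or not yb:
            continue
        sub = X_raw.iloc[keep]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _fit_unchecked(sub, ya, yb, model.n_ortho, "uv")
        except ModelError:
            continue
        v = pd.Series(_vip_values(m, variant), index=m.proteins)
        reps[i] = v.reindex(model.proteins).to_numpy()
    valid = np.isfinite(reps).all(axis=1)
    reps = reps[valid]
    k = reps.shape[0]
    if k >= 2:
        se = np.sqrt((k - 1) / k * np.sum((reps - reps.mean(axis=0)) ** 2, axis=0))
        tq = stats.t.ppf(1 - alpha / 2, k - 1)
        out["vip_lo"] = np.maximum(point - tq * se, 0.0)
        out["vip_hi"] = point + tq * se
    else:
        out["vip_lo"] = np.nan
        out["vip_hi"] = np.nan
    # the point estimate must sit inside its own interval
    out["vip_lo"] = np.minimum(out["vip_lo"], out["vip"])
    out["vip_hi"] = np.maximum(out["vip_hi"], out["vip"])
    return out


def _training_matrix(model: OplsModel) -> pd.DataFrame:
    """Raw training matrix stashed on the model at fit time (jackknife needs it)."""
    if not hasattr(model, "_x_train"):
        raise ModelError("model does not carry its training matrix")
    return model._x_train


def _vip_values(model: OplsModel, variant: str) -> np.ndarray:
    K = len(model.proteins)
    ssy_pred = float((model.t_pred @ model.t_pred) * model.c_pred**2)
    if ssy_pred <= 0 or not np.isfinite(ssy_pred):
        raise ModelError("degenerate model: zero explained class variance")
    if variant == "predictive":
        w = model.w_pred / np.linalg.norm(model.w_pred)
        return np.sqrt(K) * np.abs(w)
    if variant == "total":
        ssx = model.ssx_components
        if ssx.size == 0 or ssx.sum() <= 0:
            raise ModelError("no explained X-variance for total VIP")
        frac = ssx / ssx.sum()
        w = model.w_pred / np.linalg.norm(model.w_pred)
        acc = frac[0] * w**2
        for i in range(model.n_ortho):
            wo = model.w_ortho[i] / np.linalg.norm(model.w_ortho[i])
            acc = acc + frac[i + 1] * wo**2
        return np.sqrt(K * acc)
    raise ValueError(f"unknown VIP variant {variant!r}")


def rank_candidates(
    candidates: pd.DataFrame,
    vip: pd.DataFrame,
    *,
    primary: str = "vip",
) -> pd.DataFrame:
    """Attach VIP and dual rankings (by VIP and by |ΔTm|) to candidates.

    Candidates absent from the model input keep their |ΔTm| rank, get no VIP
    rank, and are flagged ``vip_missing``.  Ties on the primary key are
    broken by the other key, then by accession.
    """
    if primary not in ("vip", "abs_dtm"):
        raise ValueError("primary must be 'vip' or 'abs_dtm'")
    out = candidates.copy()
    out["abs_dtm"] = out["delta_tm"].abs()
    out["vip"] = vip["vip"].reindex(out.index)
    out["vip_lo"] = vip.get("vip_lo", pd.Series(dtype=float)).reindex(out.index)
    out["vip_hi"] = vip.get("vip_hi", pd.Series(dtype=float)).reindex(out.index)
    out["vip_missing"] = out["vip"].isna()
    out["rank_abs_dtm"] = (
        out["abs_dtm"].rank(ascending=False, method="first").astype("Int64")
    )
    out["rank_vip"] = out["vip"].rank(ascending=False, method="first").astype("Int64")
    keys = ["vip", "abs_dtm"] if primary == "vip" else ["abs_dtm", "vip"]
    out["_acc"] = out.index.astype(str)
    out = out.sort_values(
        keys + ["_acc"],
        ascending=[False, False, True],
        na_position="last",
        kind="stable",
    ).drop(columns="_acc")
    return out
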