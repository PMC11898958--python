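"""Train/validation splitting, OECD-style validation metrics and
applicability-domain assessment for QSRR models.

The metric suite covers goodness of fit (R2, RMSE_TR), robustness
(leave-one-out Q2_LOO, RMSE_LOO) and external predictivity (R2_EXT,
RMSE_P, Lin's concordance CCC_EXT).  Model acceptability follows the
Tropsha thresholds R2 > 0.6 and R2_EXT > 0.5.  The applicability
domain is delimited on the Williams plot: leverage h <= h* = 3p/(n-1)
and |standardized residual| <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DescriptorMatrix, QSRRModel, RetentionTable

__all__ = [
    "ValidationReport",
    "DomainAssessment",
    "split_train_validation",
    "regression_metrics",
    "loo_q2",
    "loo_cross_validate",
    "ccc_ext",
    "leverages",
    "critical_leverage",
    "williams_assessment",
    "assess_acceptability",
    "validate_split",
]

#: Tropsha acceptability thresholds
R2_MIN = 0.6
R2_EXT_MIN = 0.5


@dataclass
class ValidationReport:
    """All validation metrics for one model and one train/external split."""

    endpoint_name: str
    r2_tr: float
    rmse_tr: float
    q2_loo: float
    rmse_loo: float
    r2_ext: float
    rmse_p: float
    ccc_ext: float
    n_tr: int
    n_ext: int
    train_ids: list = field(default_factory=list)
    ext_ids: list = field(default_factory=list)
    y_obs_tr: np.ndarray | None = None
    y_fit_tr: np.ndarray | None = None
    y_cv: np.ndarray | None = None
    y_obs_ext: np.ndarray | None = None
    y_pred_ext: np.ndarray | None = None

    @property
    def metrics(self) -> dict[str, float]:
        return {
            "r2_tr": self.r2_tr,
            "rmse_tr": self.rmse_tr,
            "q2_loo": self.q2_loo,
            "rmse_loo": self.rmse_loo,
            "r2_ext": self.r2_ext,
            "rmse_p": self.rmse_p,
            "ccc_ext": self.ccc_ext,
        }

    @property
    def acceptable(self) -> dict[str, bool]:
        return assess_acceptability(self)


@dataclass
class DomainAssessment:
    """Williams-plot data: leverages and standardized residuals per compound."""

    ids: list
    sets: list  # "train" / "ext"
    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float
    in_domain: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.ids,
                "set": self.sets,
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "in_domain": self.in_domain,
            }
        )


def split_train_validation(
    table: RetentionTable | np.ndarray,
    endpoint: str | None = None,
    n_tr: int = 12,
    method: str = "ranked",
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Partition compounds into training and validation sets.

    ``method="ranked"`` sorts by the endpoint value and sends every
    third compound (the 2nd, 5th, 8th, ... in sorted order) to the
    validation set, so the endpoint extremes stay in training — a
    systematic split.  ``method="random"`` is a seeded shuffle.
    Returns positional indices into the table's record order.
    """
    if isinstance(table, RetentionTable):
        if endpoint is None:
            raise ValueError("endpoint name required for a RetentionTable")
        y = table.column(endpoint)
    else:
        y = np.asarray(table, dtype=float)
    n = y.size
    if n_tr >= n:
        raise ValueError(f"n_tr={n_tr} must be smaller than the dataset size {n}")
    if method == "ranked":
        order = np.argsort(y, kind="stable")
        val_pos = [order[i] for i in range(1, n, 3)][: n - n_tr]
        if len(val_pos) < n - n_tr:  # dataset too small for pure every-third
            rest = [i for i in order if i not in val_pos]
            val_pos += rest[: n - n_tr - len(val_pos)]
        val = sorted(int(i) for i in val_pos)
    elif method == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        val = sorted(int(i) for i in perm[n_tr:])
    else:
        raise ValueError(f"unknown split method {method!r}")
    train = [i for i in range(n) if i not in set(val)]
    return train, val


def regression_metrics(y_obs, y_pred, denominator_mean: str = "self") -> tuple[float, float]:
    """Coefficient of determination and RMSE of a prediction vector.

    R2 = 1 - sum((y_pred - y_obs)^2) / sum((y_obs - ybar)^2), with
    ``ybar`` the mean of ``y_obs`` itself (``denominator_mean="self"``,
    the literal printed form for both the training and external
    statistic).  ``denominator_mean`` may instead be a float: an
    externally supplied mean (training-mean variant of the external
    statistic).  RMSE = sqrt(mean squared error).
    """
    yo = np.asarray(y_obs, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yo.size != yp.size:
        raise ValueError("y_obs and y_pred must have equal length")
    if yo.size < 2:
        raise ValueError("need at least 2 observations")
    ybar = float(np.mean(yo)) if denominator_mean == "self" else float(denominator_mean)
    ss_tot = float(np.sum((yo - ybar) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_obs is constant: R2 denominator undefined")
    ss_res = float(np.sum((yp - yo) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / yo.size))
    return r2, rmse


def _hat_diag(design: np.ndarray) -> np.ndarray:
    # diagonal of H = X (X'X)^-1 X' via a QR factorisation
    q, _ = np.linalg.qr(design)
    return np.sum(q * q, axis=1)


def loo_q2(X_sub, y) -> tuple[np.ndarray, float, float]:
    """Leave-one-out cross-validation of an OLS fit.

    Uses the exact OLS identity e_loo,i = e_i / (1 - h_ii), so no
    refitting is required.  Returns (y_cv, q2_loo, rmse_loo).
    """
    Xs = np.atleast_2d(np.asarray(X_sub, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xs.shape
    if n < p + 3:
        raise ValueError(f"LOO needs n >= p + 3 (got n={n}, p={p})")
    design = np.column_stack([np.ones(n), Xs])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("singular design in cross-validation")
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    h = _hat_diag(design)
    if np.any(h >= 1.0 - 1e-12):
        # a leverage-one row makes its own fold singular
        bad = int(np.argmax(h))
        raise ValueError(f"LOO fold singular when leaving out row {bad}")
    e_loo = resid / (1.0 - h)
    y_cv = yv - e_loo
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant response: Q2 denominator undefined")
    press = float(np.sum(e_loo**2))
    q2 = 1.0 - press / ss_tot
    rmse_loo = float(np.sqrt(press / n))
    return y_cv, q2, rmse_loo


def loo_cross_validate(X_sub, y) -> tuple[np.ndarray, float, float]:
    """Alias of :func:`loo_q2` under the pipeline's operation name."""
    return loo_q2(X_sub, y)


def ccc_ext(y_obs, y_pred) -> float:
    """Lin's concordance correlation coefficient between observed and
    predicted values:

        CCC = 2*sum((yo - yob)(yp - ypb)) /
              [sum((yo - yob)^2) + sum((yp - ypb)^2) + n*(yob - ypb)^2]

    Penalises both scatter and systematic shift; bounded in [-1, 1].
    """
    yo = np.asarray(y_obs, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yo.size != yp.size:
        raise ValueError("vectors must have equal length")
    if yo.size < 2:
        raise ValueError("need at least 2 pairs")
    yob, ypb = yo.mean(), yp.mean()
    sxy = float(np.sum((yo - yob) * (yp - ypb)))
    sxx = float(np.sum((yo - yob) ** 2))
    syy = float(np.sum((yp - ypb) ** 2))
    if sxx == 0.0 and syy == 0.0:
        raise ValueError("both vectors constant: concordance undefined")
    denom = sxx + syy + yo.size * (yob - ypb) ** 2
    return 2.0 * sxy / denom


def leverages(X_train_sub, X_query=None) -> np.ndarray:
    """Leverage h = x'(X'X)^-1 x on the intercept-augmented training design.

    With ``X_query=None`` returns the training self-leverages (the hat
    diagonal, which sums to p+1).
    """
    Xt = np.atleast_2d(np.asarray(X_train_sub, dtype=float))
    n, p = Xt.shape
    design = np.column_stack([np.ones(n), Xt])
    xtx = design.T @ design
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("singular training design: leverages undefined")
    xtx_inv = np.linalg.inv(xtx)
    if X_query is None:
        return _hat_diag(design)
    Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
    dq = np.column_stack([np.ones(Xq.shape[0]), Xq])
    return np.einsum("ij,jk,ik->i", dq, xtx_inv, dq)


def critical_leverage(p: int, n: int) -> float:
    """Critical leverage h* = 3p/(n-1).

    ``p`` counts the model descriptors (the intercept is not counted);
    ``n`` is the training-set size.
    """
    if n <= 1:
        raise ValueError("training size n must exceed 1")
    if p < 1:
        raise ValueError("descriptor count p must be >= 1")
    return 3.0 * p / (n - 1.0)


def williams_assessment(
    model: QSRRModel,
    X_train,
    y_train,
    X_ext=None,
    y_ext=None,
    train_ids=None,
    ext_ids=None,
) -> DomainAssessment:
    """Applicability-domain assessment on the Williams plot.

    Standardized residual = residual / RMSE of the compound's own set;
    in-domain means h <= h* and |standardized residual| <= 3, both
    boundaries inclusive.
    """
    Xt = _numeric_block(X_train, model)
    yt = np.asarray(y_train, dtype=float).ravel()
    n_tr, p = Xt.shape
    h_star = critical_leverage(p, n_tr)
    h_tr = leverages(Xt)
    resid_tr = yt - model.predict(Xt)
    rmse_tr = float(np.sqrt(np.mean(resid_tr**2)))
    if rmse_tr == 0.0:
        std_tr = np.zeros_like(resid_tr)
    else:
        std_tr = resid_tr / rmse_tr

    ids = list(train_ids) if train_ids is not None else list(range(n_tr))
    sets = ["train"] * n_tr
    h_all = [h_tr]
    std_all = [std_tr]
    if X_ext is not None:
        Xe = _numeric_block(X_ext, model)
        ye = np.asarray(y_ext, dtype=float).ravel()
        h_ext = leverages(Xt, Xe)
        resid_ext = ye - model.predict(Xe)
        rmse_ext = float(np.sqrt(np.mean(resid_ext**2)))
        std_ext = resid_ext / rmse_ext if rmse_ext > 0 else np.zeros_like(resid_ext)
        ids += list(ext_ids) if ext_ids is not None else list(range(n_tr, n_tr + Xe.shape[0]))
        sets += ["ext"] * Xe.shape[0]
        h_all.append(h_ext)
        std_all.append(std_ext)
    h = np.concatenate(h_all)
    std = np.concatenate(std_all)
    in_domain = (h <= h_star) & (np.abs(std) <= 3.0)
    return DomainAssessment(
        ids=ids, sets=sets, leverage=h, std_residual=std, h_star=h_star, in_domain=in_domain
    )


def _numeric_block(X, model: QSRRModel) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        X = X.frame
    if isinstance(X, pd.DataFrame):
        return X[model.descriptor_names].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float))


def assess_acceptability(report) -> dict[str, bool]:
    """Tropsha acceptability: R2 > 0.6 on training and R2_EXT > 0.5."""
    r2 = report.r2_tr if hasattr(report, "r2_tr") else report["r2_tr"]
    r2_ext = report.r2_ext if hasattr(report, "r2_ext") else report["r2_ext"]
    flags = {"r2_ok": bool(r2 > R2_MIN), "r2_ext_ok": bool(r2_ext > R2_EXT_MIN)}
    flags["overall"] = flags["r2_ok"] and flags["r2_ext_ok"]
    return flags


def validate_split(
    X_train,
    y_train,
    X_ext,
    y_ext,
    endpoint_name: str = "y",
    train_ids=None,
    ext_ids=None,
    ext_denominator_mean: str = "self",
) -> tuple[ValidationReport, QSRRModel]:
    """Fit on the training rows and compute the full metric suite.

    ``ext_denominator_mean="self"`` uses the external-set mean in the
    R2_EXT denominator (the default, literal form); pass ``"train"``
    for the training-mean variant.
    """
    from .gamlr import fit_mlr  # local import: gamlr depends on this module

    model = fit_mlr(X_train, y_train, endpoint_name=endpoint_name)
    yt = np.asarray(y_train, dtype=float).ravel()
    ye = np.asarray(y_ext, dtype=float).ravel()
    Xt = _numeric_block(X_train, model)
    Xe = _numeric_block(X_ext, model)

    y_fit = model.predict(Xt)
    r2_tr, rmse_tr = regression_metrics(yt, y_fit)
    y_cv, q2, rmse_loo = loo_q2(Xt, yt)
    y_pred = model.predict(Xe)
    denom = "self" if ext_denominator_mean == "self" else float(np.mean(yt))
    r2_ext, rmse_p = regression_metrics(ye, y_pred, denominator_mean=denom)
    ccc = ccc_ext(ye, y_pred)

    report = ValidationReport(
        endpoint_name=endpoint_name,
        r2_tr=r2_tr,
        rmse_tr=rmse_tr,
        q2_loo=q2,
        rmse_loo=rmse_loo,
        r2_ext=r2_ext,
        rmse_p=rmse_p,
        ccc_ext=ccc,
        n_tr=yt.size,
        n_ext=ye.size,
        train_ids=list(train_ids) if train_ids is not None else list(range(yt.size)),
        ext_ids=list(ext_ids) if ext_ids is not None else list(range(ye.size)),
        y_obs_tr=yt,
        y_fit_tr=y_fit,
        y_cv=y_cv,
        y_obs_ext=ye,
        y_pred_ext=y_pred,
    )
    return report, model
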