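"""REML variance components for line and genomic mixed models.

Two model families share one average-information REML engine:

* the line model  Y = mu + day + block + plate + L + E  with i.i.d. line
  effects (broad-sense heritability H^2 = sigma_L^2/(sigma_L^2+sigma_E^2)),
* one- and two-component genomic models  y = Xb + Z g + e  with
  Cov(g) = G sigma_g^2 (GBLUP) or Cov(g) = G_f sigma_f^2 + G_r sigma_r^2
  (GFBLUP), where Z maps repeated records to lines.

The covariance structure V = Z K Z' sigma + I sigma_e^2 is inverted through
the Woodbury identity, so every solve is at the line level (q x q) even
though the likelihood is defined on the full record vector.  The AI update is
step-halved against the restricted likelihood, with a fixed-point fallback,
and components are clamped at a small positive floor rather than allowed to
go negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .grm import GRM

logger = logging.getLogger(__name__)

DESIGN_FACTORS = ("day", "block", "plate")
VC_FLOOR_FRAC = 1e-8  # lower bound as a fraction of phenotypic variance
MAX_ITER = 200
TOL = 1e-6


class DesignError(ValueError):
    pass


@dataclass
class VarianceEstimate:
    """Converged (or flagged) REML fit with BLUPs and residuals."""

    components: dict[str, float]
    beta: pd.Series
    g_by_component: dict[str, np.ndarray]
    g_total: np.ndarray
    e_hat: np.ndarray = field(repr=False)
    fitted_fixed: np.ndarray = field(repr=False)
    line_ids: list[str]
    record_lines: np.ndarray = field(repr=False)  # per-record index into line_ids
    loglik: float
    n_iter: int
    converged: bool
    ll_trace: list[float] = field(repr=False, default_factory=list)

    @classmethod
    def from_components(cls, components: dict[str, float]) -> "VarianceEstimate":
        """Wrap externally known variance components (no data attached).

        Useful for computing heritability ratios from published fractions.
        """
        empty = np.array([])
        return cls(
            components=dict(components), beta=pd.Series(dtype=float),
            g_by_component={}, g_total=empty, e_hat=empty, fitted_fixed=empty,
            line_ids=[], record_lines=empty.astype(int), loglik=np.nan,
            n_iter=0, converged=True,
        )

    @property
    def genomic_variance(self) -> float:
        """Total among-line genetic variance across random components."""
        return sum(v for k, v in self.components.items() if k != "residual")


@dataclass
class HeritabilityReport:
    """Heritability ratios derived from a variance-component fit.

    ``H2_individual`` is the among-line fraction of individual-record
    variance; ``H2_line_means`` rescales the residual by the mean replicate
    count n_bar, sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_bar).
    """

    H2_individual: float
    H2_line_means: float | None = None
    n_bar: float | None = None
    h2_gblup: float | None = None
    h2_gfblup: float | None = None
    h2_f: float | None = None
    h2_r: float | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__, dtype=float)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(pheno: pd.DataFrame, factors: tuple[str, ...] = ()) -> tuple[np.ndarray, list[str]]:
    """Intercept plus reference-level indicator coding for the named factors.

    Raises :class:`DesignError` listing aliased columns if the matrix is
    rank-deficient after coding.
    """
    n = len(pheno)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for fac in factors:
        dummies = pd.get_dummies(pheno[fac].astype("category"), prefix=fac, drop_first=True)
        blocks.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        aliased = [names[j] for j in piv[rank:]]
        raise DesignError(f"singular fixed-effect design; aliased columns: {aliased}")
    return X, names


def _line_incidence(pheno: pd.DataFrame, line_ids: list[str]) -> np.ndarray:
    pos = {lid: i for i, lid in enumerate(line_ids)}
    try:
        return np.array([pos[lid] for lid in pheno["line_id"].astype(str)])
    except KeyError as exc:
        raise DesignError(f"record line {exc} absent from the line list") from exc


# ---------------------------------------------------------------------------
# AI-REML engine
# ---------------------------------------------------------------------------

class _Woodbury:
    """Solves with V = sigma_e^2 I + Z K Z' at the line level.

    Uses V^-1 = (I - Z B Z')/sigma_e^2 with B = K (sigma_e^2 I + D K)^-1,
    where D = diag(records per line).
    """

    def __init__(self, theta: np.ndarray, Ks: list[np.ndarray], D: np.ndarray,
                 rec_line: np.ndarray):
        self.sig_e = theta[-1]
        q = len(D)
        K = np.zeros((q, q))
        for t, Kk in zip(theta[:-1], Ks):
            K += t * Kk
        A = self.sig_e * np.eye(q) + D[:, None] * K
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("V is not positive definite")
        self.B = K @ np.linalg.inv(A)
        self.D = D
        self.rec_line = rec_line
        self.N = len(rec_line)
        self.logdet_V = (self.N - q) * np.log(self.sig_e) + logdet_A
        self.K = K

    def Zt(self, M: np.ndarray) -> np.ndarray:
        """Z' M for a record-level vector or matrix."""
        q = len(self.D)
        if M.ndim == 1:
            return np.bincount(self.rec_line, weights=M, minlength=q)
        out = np.zeros((q, M.shape[1]))
        np.add.at(out, self.rec_line, M)
        return out

    def vinv(self, M: np.ndarray) -> np.ndarray:
        """V^-1 M."""
        return (M - (self.B @ self.Zt(M))[self.rec_line]) / self.sig_e

    def zt_vinv_z(self) -> np.ndarray:
        D = self.D
        return (np.diag(D) - (D[:, None] * self.B) * D[None, :]) / self.sig_e

    def tr_vinv(self) -> float:
        return (self.N - float(np.diag(self.B) @ self.D)) / self.sig_e


def _reml_pieces(theta, y, X, Ks, D, rec_line):
    """Restricted log-likelihood (constant-free) and the P-projected pieces."""
    wb = _Woodbury(theta, Ks, D, rec_line)
    U = wb.vinv(X)
    C = X.T @ U
    sign, logdet_C = np.linalg.slogdet(C)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X is singular")
    C_fac = scipy.linalg.cho_factor(C)
    Vinv_y = wb.vinv(y)
    beta = scipy.linalg.cho_solve(C_fac, X.T @ Vinv_y)
    Py = Vinv_y - U @ beta
    ll = -0.5 * (wb.logdet_V + logdet_C + float(y @ Py))
    return wb, U, C_fac, beta, Py, ll


def _reml_loglik(theta, y, X, Ks, D, rec_line) -> float:
    try:
        return _reml_pieces(theta, y, X, Ks, D, rec_line)[-1]
    except np.linalg.LinAlgError:
        return -np.inf


def ai_reml(y: np.ndarray, X: np.ndarray, rec_line: np.ndarray,
            Ks: list[np.ndarray], *, max_iter: int = MAX_ITER, tol: float = TOL,
            ) -> dict:
    """Average-information REML for V = sum_k Z K_k Z' theta_k + I theta_e.

    Components are initialized at var(y)/(n_components) and floored at
    ``VC_FLOOR_FRAC`` times the phenotypic variance.  The AI step is halved
    (up to 10 times) whenever it would decrease the restricted likelihood,
    then a fixed-point update theta_k <- theta_k * (y'P dV_k P y)/tr(P dV_k)
    is tried; if nothing improves the likelihood the iteration stops.
    """
    y = np.asarray(y, dtype=float)
    q = max(rec_line) + 1
    D = np.bincount(rec_line, minlength=q).astype(float)
    n_comp = len(Ks) + 1
    var_y = float(np.var(y, ddof=1))
    floor = VC_FLOOR_FRAC * var_y
    theta = np.full(n_comp, var_y / n_comp)

    wb, U, C_fac, beta, Py, ll = _reml_pieces(theta, y, X, Ks, D, rec_line)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # score and AI matrix at the current theta
        ZtPy = wb.Zt(Py)
        ZtU = wb.Zt(U)
        ZtVinvZ = wb.zt_vinv_z()
        F = np.empty((len(y), n_comp))
        tr_P = np.empty(n_comp)
        for k, Kk in enumerate(Ks):
            F[:, k] = (Kk @ ZtPy)[rec_line]
            t1 = float(np.sum(Kk * ZtVinvZ.T))
            corr = float(np.trace(scipy.linalg.cho_solve(C_fac, ZtU.T @ Kk @ ZtU)))
            tr_P[k] = t1 - corr
        F[:, -1] = Py
        tr_P[-1] = wb.tr_vinv() - float(np.trace(scipy.linalg.cho_solve(C_fac, U.T @ U)))
        quad = F.T @ Py
        score = -0.5 * (tr_P - quad)
        PF = wb.vinv(F) - U @ scipy.linalg.cho_solve(C_fac, U.T @ F)
        AI = 0.5 * (F.T @ PF)
        AI = (AI + AI.T) / 2.0

        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(n_comp), score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-12)

        accepted = None
        best_ll = -np.inf
        step = 1.0
        for _ in range(11):  # full step + up to 10 halvings
            cand = np.maximum(theta + step * delta, floor)
            ll_cand = _reml_loglik(cand, y, X, Ks, D, rec_line)
            best_ll = max(best_ll, ll_cand)
            if ll_cand >= ll - 1e-12:
                accepted = (cand, ll_cand)
                break
            step /= 2.0
        if accepted is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(tr_P > 0, quad / tr_P, 1.0)
            cand = np.maximum(theta * ratio, floor)
            ll_cand = _reml_loglik(cand, y, X, Ks, D, rec_line)
            best_ll = max(best_ll, ll_cand)
            if ll_cand >= ll - 1e-12:
                accepted = (cand, ll_cand)
        if accepted is None:
            # likelihood flat to tolerance in every direction tried: converged
            if abs(best_ll - ll) < tol:
                converged = True
            else:
                logger.warning("AI-REML: no improving step at iteration %d; stopping", it)
            break

        new_theta, new_ll = accepted
        d_ll = new_ll - ll
        rel = np.max(np.abs(new_theta - theta) / np.maximum(new_theta, floor))
        theta, ll = new_theta, new_ll
        trace.append(ll)
        wb, U, C_fac, beta, Py, ll = _reml_pieces(theta, y, X, Ks, D, rec_line)
        if abs(d_ll) < tol and rel < tol:
            converged = True
            break

    # BLUPs at the converged components: u_k = theta_k K_k Z' P y
    ZtPy = wb.Zt(Py)
    g_by_comp = [theta[k] * (Kk @ ZtPy) for k, Kk in enumerate(Ks)]
    e_hat = theta[-1] * Py
    return {
        "theta": theta, "beta": beta, "loglik": ll, "trace": trace,
        "n_iter": it, "converged": converged, "g_by_component": g_by_comp,
        "e_hat": e_hat, "Py": Py,
    }


# ---------------------------------------------------------------------------
# Public model fits
# ---------------------------------------------------------------------------

def _check_psd(grm: GRM, tol: float = 1e-8) -> None:
    w = np.linalg.eigvalsh(grm.G)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"GRM '{grm.label}' is not positive semidefinite "
                         f"(min eigenvalue {w.min():.3g})")


def _finish(res: dict, names: list[str], comp_names: list[str],
            line_ids: list[str], rec_line: np.ndarray, X: np.ndarray) -> VarianceEstimate:
    components = dict(zip(comp_names, res["theta"][:-1]))
    components["residual"] = float(res["theta"][-1])
    g_by = {n: g for n, g in zip(comp_names, res["g_by_component"])}
    g_total = np.sum(list(g_by.values()), axis=0)
    if not res["converged"]:
        logger.warning("REML did not converge in %d iterations", res["n_iter"])
    return VarianceEstimate(
        components={k: float(v) for k, v in components.items()},
        beta=pd.Series(res["beta"], index=names),
        g_by_component=g_by,
        g_total=g_total,
        e_hat=res["e_hat"],
        fitted_fixed=X @ res["beta"],
        line_ids=list(line_ids),
        record_lines=rec_line,
        loglik=res["loglik"],
        n_iter=res["n_iter"],
        converged=res["converged"],
        ll_trace=res["trace"],
    )


def fit_line_model(pheno: pd.DataFrame, factors: tuple[str, ...] | None = None,
                   ) -> VarianceEstimate:
    """REML fit of Y = mu + day + block + plate + L + E with i.i.d. line
    effects, for broad-sense heritability."""
    if factors is None:
        factors = tuple(f for f in DESIGN_FACTORS if f in pheno.columns)
    line_ids = list(dict.fromkeys(pheno["line_id"].astype(str)))
    if len(line_ids) < 2:
        raise DesignError("need at least 2 lines")
    rec_line = _line_incidence(pheno, line_ids)
    X, names = build_design(pheno, factors)
    y = pheno["value"].to_numpy(dtype=float)
    res = ai_reml(y, X, rec_line, [np.eye(len(line_ids))])
    return _finish(res, names, ["line"], line_ids, rec_line, X)


def fit_genomic_model(pheno: pd.DataFrame, grms: list[GRM],
                      factors: tuple[str, ...] = (), *, check_psd: bool = True,
                      ) -> VarianceEstimate:
    """AI-REML fit of the GBLUP (one GRM) or GFBLUP (feature + remainder)
    model on records with repeated measures per line.

    ``pheno`` needs ``line_id`` and ``value`` columns; lines are matched to
    the GRMs by id, and the GRMs are subset to the lines present in the
    records (training-fold fits pass only training records).
    """
    if not 1 <= len(grms) <= 2:
        raise ValueError("expected 1 or 2 relationship matrices")
    if len(grms) == 2 and grms[0].line_ids != grms[1].line_ids:
        raise ValueError("GRMs must share an identical line ordering")
    if check_psd:
        for g in grms:
            _check_psd(g)
    present = set(pheno["line_id"].astype(str))
    line_ids = [lid for lid in grms[0].line_ids if lid in present]
    missing = present - set(line_ids)
    if missing:
        raise DesignError(f"records for lines absent from GRM: {sorted(missing)[:5]}")
    sel = np.array([grms[0].line_ids.index(lid) for lid in line_ids])
    Ks = [g.G[np.ix_(sel, sel)] for g in grms]
    comp_names = ["genomic"] if len(grms) == 1 else [grms[0].label, grms[1].label]
    rec_line = _line_incidence(pheno, line_ids)
    X, names = build_design(pheno, factors)
    y = pheno["value"].to_numpy(dtype=float)
    res = ai_reml(y, X, rec_line, Ks)
    return _finish(res, names, comp_names, line_ids, rec_line, X)


def adjust_phenotypes(est: VarianceEstimate, pheno: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect-adjusted records  y~_ij = g^_i + e^_ij  =  y_ij - (Xb)_ij.

    The two forms are algebraically identical for a BLUP fit; the subtraction
    form is used so the identity can be asserted against the BLUP pieces.
    """
    if len(pheno) != len(est.fitted_fixed):
        raise DesignError("phenotype table does not match the fitted records")
    out = pheno.copy()
    out["value"] = pheno["value"].to_numpy(dtype=float) - est.fitted_fixed
    return out


def heritability_report(est: VarianceEstimate, n_bar: float | None = None,
                        ) -> HeritabilityReport:
    """Heritability ratios from a variance-component estimate.

    The among-line (genomic or line) variance is summed across random
    components; the line-mean broad-sense heritability divides the residual
    by the mean replicate count n_bar.
    """
    if not est.converged:
        logger.warning("heritability requested from a non-converged fit")
    comp = est.components
    sig_e = comp["residual"]
    sig_g = est.genomic_variance
    rep = HeritabilityReport(H2_individual=sig_g / (sig_g + sig_e))
    if n_bar is not None:
        rep.n_bar = float(n_bar)
        rep.H2_line_means = sig_g / (sig_g + sig_e / n_bar)
    if "genomic" in comp:
        rep.h2_gblup = comp["genomic"] / (comp["genomic"] + sig_e)
    if "feature" in comp and "remainder" in comp:
        f, r = comp["feature"], comp["remainder"]
        rep.h2_gfblup = (f + r) / (f + r + sig_e)
        rep.h2_f = f / (f + r)
        rep.h2_r = r / (f + r)
    return rep


def write_fit_summary(est: VarianceEstimate, path, n_bar: float | None = None) -> None:
    """Persist a fit as TSV: components block plus heritability ratios."""
    rows = [("component:" + k, v) for k, v in est.components.items()]
    rep = heritability_report(est, n_bar)
    rows += [("ratio:" + k, v) for k, v in rep.to_series().dropna().items()]
    rows += [("loglik", est.loglik), ("n_iter", est.n_iter),
             ("converged", float(est.converged))]
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(path, sep="\t", index=False)
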