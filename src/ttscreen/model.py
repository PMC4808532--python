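"""Per-site linear models for epigenome-wide screening.

Every screening route in this package (training/testing resampling, FDR,
Bonferroni) rests on the same primitive: regress each CpG site's M-value
profile on a shared design matrix and extract one p-value per model term.
Because the design matrix is common to all sites, the whole panel is fitted
in a single pass — one QR factorisation of the design, then triangular
solves against the full response matrix — rather than looping a scalar
regression routine over tens of thousands of sites.

Two engines are provided:

* ``ols`` — ordinary least squares. Single-column terms are tested with a
  two-sided t statistic on the residual degrees of freedom; multi-column
  terms (a categorical main effect, or an interaction involving one) with a
  partial F test against the model with that term's columns removed.
* ``robust`` — Huber M-estimation (tuning constant 1.345, MAD scale,
  iteratively reweighted least squares, at most 50 iterations, coefficient
  tolerance 1e-8). Term p-values come from asymptotic normal / chi-squared
  Wald statistics on the Huber sandwich covariance. A site that fails to
  converge is flagged and its p-values are set to 1 so it can never pass a
  significance gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)

HUBER_C = 1.345
HUBER_MAX_ITER = 50
HUBER_TOL = 1e-8
_MAD_SCALE = 0.6744897501960817  # Phi^{-1}(3/4): makes MAD consistent for the normal sd
_RANK_TOL = 1e-10

__all__ = [
    "MethylationMatrix",
    "DesignSpec",
    "DesignMatrix",
    "SiteFit",
    "RankDeficientDesignError",
    "build_design_matrix",
    "fit_sites",
    "term_pvalues",
    "partial_f_pvalue",
]


class RankDeficientDesignError(ValueError):
    """Design matrix is not full column rank on the samples being fitted."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(self.columns)
        )


@dataclass
class MethylationMatrix:
    """Sites x samples panel of methylation M-values.

    M-values (log2 ratios of methylated to unmethylated probe intensity) are
    unbounded reals, so no range restriction is imposed — but missing values
    are rejected outright; imputation is the loader's job (see
    :func:`ttscreen.io.load_methylation`).
    """

    site_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.site_ids)) != len(self.site_ids):
            dup = pd.Index(self.site_ids)
            dup = sorted(set(dup[dup.duplicated()]))
            raise ValueError(f"duplicate site id(s): {', '.join(dup)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("M-value matrix contains missing/non-finite entries")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MethylationMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None


@dataclass
class DesignSpec:
    """Model specification: covariate table, terms, and the term(s) of interest.

    ``terms`` is an ordered list of model terms — a main effect names one
    covariate column, an interaction is written ``"a:b"``. ``interest`` is the
    non-empty subset of terms whose p-values gate site selection (e.g. the
    x1:x2 interaction). ``sv_matrix`` (samples x n_sv), when present, is
    appended to every design matrix as adjustment columns SV1..SVk.

    Categorical covariates are detected from the column dtype (anything
    non-numeric, or pandas Categorical) or can be forced via ``categorical``;
    they expand to reference-coded indicators with the first sorted level as
    reference. Levels are fixed from the *complete* covariate table so the
    coding is identical on every train/test subset.
    """

    covariates: pd.DataFrame
    terms: list[str]
    interest: list[str]
    sv_matrix: np.ndarray | None = None
    categorical: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.terms = list(self.terms)
        self.interest = list(self.interest)
        self.categorical = frozenset(self.categorical)
        if not self.terms:
            raise ValueError("terms must be non-empty")
        if not self.interest:
            raise ValueError("interest must be non-empty")
        missing = [t for t in self.interest if t not in self.terms]
        if missing:
            raise ValueError(f"interest term(s) not in terms: {missing}")
        for term in self.terms:
            for name in term.split(":"):
                if name not in self.covariates.columns:
                    raise ValueError(
                        f"term {term!r} references unknown covariate {name!r}"
                    )
        unknown = self.categorical - set(self.covariates.columns)
        if unknown:
            raise ValueError(f"categorical names not in covariates: {sorted(unknown)}")
        if self.sv_matrix is not None:
            self.sv_matrix = np.asarray(self.sv_matrix, dtype=float)
            if self.sv_matrix.ndim != 2 or self.sv_matrix.shape[0] != len(self.covariates):
                raise ValueError("sv_matrix must be (n_samples, n_sv)")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.covariates.index]

    @property
    def n_sv(self) -> int:
        return 0 if self.sv_matrix is None else self.sv_matrix.shape[1]

    def is_categorical(self, name: str) -> bool:
        if name in self.categorical:
            return True
        return not pd.api.types.is_numeric_dtype(self.covariates[name])

    def with_svs(self, sv_matrix: np.ndarray | None) -> "DesignSpec":
        return DesignSpec(
            self.covariates, self.terms, self.interest, sv_matrix, self.categorical
        )

    def without_svs(self) -> "DesignSpec":
        return self.with_svs(None)


@dataclass
class DesignMatrix:
    """Realised numeric design for a given set of samples."""

    X: np.ndarray
    columns: list[str]
    term_columns: dict[str, np.ndarray]  # term -> column indices into X
    sample_ids: list[str]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _encode_main(design: DesignSpec, name: str, rows: np.ndarray) -> tuple[list[str], np.ndarray]:
    col = design.covariates[name]
    if design.is_categorical(name):
        levels = np.unique(np.asarray(col.astype(str)))
        sub = np.asarray(col.astype(str))[rows]
        cols = [f"{name}[{lv}]" for lv in levels[1:]]
        mat = np.column_stack([(sub == lv).astype(float) for lv in levels[1:]]) \
            if len(levels) > 1 else np.empty((len(rows), 0))
        return cols, mat
    return [name], np.asarray(col, dtype=float)[rows][:, None]


def build_design_matrix(design: DesignSpec, sample_ids: Sequence[str] | None = None) -> DesignMatrix:
    """Build the numeric design matrix (intercept, terms, SVs) for a sample subset.

    Raises :class:`RankDeficientDesignError` if the resulting matrix is not
    of full column rank on these samples, naming the offending columns.
    """
    all_ids = design.sample_ids
    if sample_ids is None:
        sample_ids = all_ids
    sample_ids = [str(s) for s in sample_ids]
    pos = {s: i for i, s in enumerate(all_ids)}
    try:
        rows = np.array([pos[s] for s in sample_ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"sample id {exc.args[0]!r} not in covariate table") from None

    blocks: list[np.ndarray] = [np.ones((len(rows), 1))]
    columns: list[str] = ["Intercept"]
    term_columns: dict[str, np.ndarray] = {}
    start = 1
    for term in design.terms:
        parts = term.split(":")
        if len(parts) == 1:
            names, mat = _encode_main(design, parts[0], rows)
        elif len(parts) == 2:
            n_a, m_a = _encode_main(design, parts[0], rows)
            n_b, m_b = _encode_main(design, parts[1], rows)
            names = [f"{a}:{b}" for a in n_a for b in n_b]
            mat = (m_a[:, :, None] * m_b[:, None, :]).reshape(len(rows), -1)
        else:
            raise ValueError(f"only pairwise interactions supported: {term!r}")
        blocks.append(mat)
        columns.extend(names)
        term_columns[term] = np.arange(start, start + mat.shape[1])
        start += mat.shape[1]
    if design.sv_matrix is not None and design.n_sv:
        blocks.append(design.sv_matrix[rows])
        columns.extend(f"SV{i + 1}" for i in range(design.n_sv))
        start += design.n_sv

    X = np.hstack(blocks)
    _check_full_rank(X, columns)
    return DesignMatrix(X, columns, term_columns, sample_ids)


def _check_full_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficientDesignError(columns)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * _RANK_TOL * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = sorted(columns[i] for i in piv[rank:])
        raise RankDeficientDesignError(bad)


# ---------------------------------------------------------------------------
# OLS engine
# ---------------------------------------------------------------------------


@dataclass
class _OlsFit:
    coef: np.ndarray        # (p, n_sites)
    rss: np.ndarray         # (n_sites,)
    df_resid: int
    xtx_inv: np.ndarray     # (p, p)
    converged: np.ndarray   # (n_sites,) bool — always True for OLS

    @property
    def sigma2(self) -> np.ndarray:
        return self.rss / self.df_resid

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.xtx_inv)[:, None] * self.sigma2[None, :])


def _ols_fit(X: np.ndarray, Y: np.ndarray) -> _OlsFit:
    """Fit all sites at once: Y is (n_sites, n_samples)."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) <= max(X.shape) * _RANK_TOL * np.max(np.abs(np.diag(R))):
        # caller should have validated; re-derive names lazily
        raise RankDeficientDesignError([f"column {i}" for i in range(p)])
    Yt = Y.T  # (n, n_sites)
    coef = linalg.solve_triangular(R, Q.T @ Yt)
    resid = Yt - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    r_inv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv = r_inv @ r_inv.T
    return _OlsFit(coef, rss, n - p, xtx_inv, np.ones(Y.shape[0], dtype=bool))


def _rss_reduced(X_reduced: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RSS per site of the reduced model, via projection onto its Q basis."""
    Q, _ = np.linalg.qr(X_reduced)
    Yt = Y.T
    total = np.einsum("ij,ij->j", Yt, Yt)
    proj = Q.T @ Yt
    return total - np.einsum("ij,ij->j", proj, proj)


def partial_f_pvalue(
    rss_full: np.ndarray,
    rss_reduced: np.ndarray,
    df_resid: int,
    df_term: int,
) -> np.ndarray:
    """Partial F-test p-value(s) comparing nested OLS fits.

    For a one-column term this reduces exactly to the squared-t test.
    Raises if the reduced RSS falls below the full RSS by more than
    numerical tolerance (the models would not be nested).
    """
    rss_full = np.asarray(rss_full, dtype=float)
    rss_reduced = np.asarray(rss_reduced, dtype=float)
    tol = 1e-8 * np.maximum(rss_full, 1.0)
    if np.any(rss_reduced < rss_full - tol):
        raise FloatingPointError(
            "reduced-model RSS below full-model RSS: models are not nested"
        )
    diff = np.clip(rss_reduced - rss_full, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (diff / df_term) / (rss_full / df_resid)
    f_stat = np.where(rss_full <= 0, np.inf, f_stat)
    return stats.f.sf(f_stat, df_term, df_resid)


def _ols_term_pvalues(
    dm: DesignMatrix, Y: np.ndarray, terms: Sequence[str], fit: _OlsFit
) -> dict[str, np.ndarray]:
    pvals: dict[str, np.ndarray] = {}
    se = None
    for term in terms:
        cols = dm.term_columns[term]
        if len(cols) == 1:
            if se is None:
                se = fit.standard_errors()
            j = cols[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = fit.coef[j] / se[j]
            t = np.where(se[j] == 0, np.inf * np.sign(fit.coef[j]), t)
            pvals[term] = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
        else:
            X_red = np.delete(dm.X, cols, axis=1)
            rss_red = _rss_reduced(X_red, Y)
            pvals[term] = partial_f_pvalue(fit.rss, rss_red, fit.df_resid, len(cols))
    return pvals


# ---------------------------------------------------------------------------
# Robust (Huber) engine
# ---------------------------------------------------------------------------


@dataclass
class _HuberFit:
    coef: np.ndarray        # (p, n_sites)
    cov: np.ndarray         # (n_sites, p, p) asymptotic covariance of coef
    converged: np.ndarray   # (n_sites,) bool
    df_resid: int

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.einsum("sii->is", self.cov))


def _huber_fit(X: np.ndarray, Y: np.ndarray) -> _HuberFit:
    """Huber IRLS across all sites simultaneously (batched normal equations)."""
    n, p = X.shape
    n_sites = Y.shape[0]
    beta = _ols_fit(X, Y).coef  # (p, n_sites) starting values
    converged = np.zeros(n_sites, dtype=bool)
    Yt = Y.T
    w = np.ones((n, n_sites))
    for _ in range(HUBER_MAX_ITER):
        resid = Yt - X @ beta
        scale = np.median(np.abs(resid), axis=0) / _MAD_SCALE
        scale = np.maximum(scale, 1e-12)
        u = resid / scale
        w = np.minimum(1.0, HUBER_C / np.maximum(np.abs(u), 1e-300))
        xtwx = np.einsum("np,ns,nq->spq", X, w, X, optimize=True)
        xtwy = np.einsum("np,ns,ns->sp", X, w, Yt, optimize=True)
        beta_new = np.linalg.solve(xtwx, xtwy[:, :, None])[:, :, 0].T  # (p, n_sites)
        delta = np.max(np.abs(beta_new - beta), axis=0)
        beta = beta_new
        converged = delta < HUBER_TOL
        if converged.all():
            break
    if not converged.all():
        logger.warning(
            "robust fit did not converge at %d/%d site(s); their p-values are set to 1",
            int((~converged).sum()),
            n_sites,
        )
    # Huber sandwich covariance: s^2 * E[psi^2] / E[psi']^2 * (X'X)^-1, with a
    # small-sample n/(n-p) correction.
    resid = Yt - X @ beta
    scale = np.maximum(np.median(np.abs(resid), axis=0) / _MAD_SCALE, 1e-12)
    u = resid / scale
    psi = np.clip(u, -HUBER_C, HUBER_C)
    psi_prime = (np.abs(u) <= HUBER_C).astype(float)
    num = scale**2 * np.mean(psi**2, axis=0)
    den = np.maximum(np.mean(psi_prime, axis=0), 1e-12) ** 2
    xtx_inv = np.linalg.inv(X.T @ X)
    factor = (n / (n - p)) * num / den  # (n_sites,)
    cov = factor[:, None, None] * xtx_inv[None, :, :]
    return _HuberFit(beta, cov, converged, n - p)


def _huber_term_pvalues(
    dm: DesignMatrix, terms: Sequence[str], fit: _HuberFit
) -> dict[str, np.ndarray]:
    pvals: dict[str, np.ndarray] = {}
    se = fit.standard_errors()
    for term in terms:
        cols = dm.term_columns[term]
        if len(cols) == 1:
            j = cols[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                z = fit.coef[j] / se[j]
            p = 2.0 * stats.norm.sf(np.abs(z))
        else:
            b = fit.coef[cols, :].T[:, :, None]  # (n_sites, q, 1)
            sub = fit.cov[:, cols[:, None], cols[None, :]]
            wald = np.einsum(
                "sqa,sqr,sra->s", b, np.linalg.inv(sub), b
            )
            p = stats.chi2.sf(wald, len(cols))
        p = np.where(fit.converged, p, 1.0)
        pvals[term] = p
    return pvals


# ---------------------------------------------------------------------------
# Public fitting surface
# ---------------------------------------------------------------------------


@dataclass
class SiteFit:
    """Fitted per-site regression: coefficients, SEs, and per-term p-values."""

    site_id: str
    coefficients: pd.Series
    standard_errors: pd.Series
    term_pvalues: dict[str, float]
    converged: bool = True


def term_pvalues(
    M: MethylationMatrix,
    design: DesignSpec,
    samples: Sequence[str] | None = None,
    engine: str = "ols",
    terms: Sequence[str] | None = None,
    site_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, object, DesignMatrix]:
    """Per-term p-values for every (masked) site, plus the underlying fit.

    This is the fast path used by the screening loop; :func:`fit_sites`
    wraps it into per-site objects. Returns ``(pvalues, fit, design_matrix)``
    where ``pvalues`` is a sites x terms DataFrame.
    """
    if engine not in ("ols", "robust"):
        raise ValueError(f"unknown engine {engine!r}")
    dm = build_design_matrix(design, samples)
    if len(dm.sample_ids) <= dm.n_columns + 1:
        raise ValueError(
            f"need more than {dm.n_columns + 1} samples to fit a "
            f"{dm.n_columns}-column design; got {len(dm.sample_ids)}"
        )
    idx = M.sample_indices(dm.sample_ids)
    Y = M.values[:, idx]
    site_ids = M.site_ids
    if site_mask is not None:
        Y = Y[site_mask]
        site_ids = [s for s, keep in zip(M.site_ids, site_mask) if keep]
    if terms is None:
        terms = design.terms
    if engine == "ols":
        fit = _ols_fit(dm.X, Y)
        pvals = _ols_term_pvalues(dm, Y, terms, fit)
    else:
        fit = _huber_fit(dm.X, Y)
        pvals = _huber_term_pvalues(dm, terms, fit)
    frame = pd.DataFrame(pvals, index=site_ids, columns=list(terms))
    return frame, fit, dm


def fit_sites(
    M: MethylationMatrix,
    design: DesignSpec,
    samples: Sequence[str] | None = None,
    engine: str = "ols",
) -> list[SiteFit]:
    """Fit the model at every site on the given sample subset.

    One :class:`SiteFit` per site, in the matrix's site order; p-values cover
    every term in ``design.terms``.
    """
    pvals, fit, dm = term_pvalues(M, design, samples, engine)
    se = fit.standard_errors()
    out: list[SiteFit] = []
    for i, site in enumerate(M.site_ids):
        out.append(
            SiteFit(
                site_id=site,
                coefficients=pd.Series(fit.coef[:, i], index=dm.columns),
                standard_errors=pd.Series(se[:, i], index=dm.columns),
                term_pvalues={t: float(pvals.iloc[i][t]) for t in design.terms},
                converged=bool(fit.converged[i]),
            )
        )
    return out
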