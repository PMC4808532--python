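"""Surrogate variable analysis: how many hidden covariates, and what are they.

Methylation panels carry systematic variation (batch, cell composition,
unmeasured exposures) that is not in the stated model. Surrogate variables
(SVs) are estimated directly from the data and appended to the design as
adjustment covariates.

Two operations:

* :func:`estimate_num_sv` — permutation (parallel-analysis) estimate of the
  number of SVs. The M-value matrix is residualised on the design per site;
  a right singular vector of the residual matrix counts as a surrogate
  variable if the fraction of variance it explains exceeds what is seen when
  each site's residuals are independently shuffled across samples
  (destroying any shared structure). Components are examined in order of
  decreasing variance and counting stops at the first non-significant one.
* :func:`estimate_sv_twostep` — the two-step construction. Step 1 takes the
  leading right singular vectors of the residual matrix. Step 2, for each
  such vector, finds the sites whose residuals are significantly associated
  with it and re-extracts the surrogate variable from the *original*
  (non-residualised) data restricted to those sites, picking the singular
  vector most correlated with the step-1 vector. The result is
  orthonormalised with a fixed sign convention.

SVs are intended to be estimated once, on the complete data, and reused
across all train/test iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .model import DesignSpec, MethylationMatrix, build_design_matrix

logger = logging.getLogger(__name__)

__all__ = ["SurrogateSet", "estimate_num_sv", "estimate_sv_twostep", "attach_svs"]

#: permutation count and per-component significance level for estimate_num_sv
DEFAULT_N_PERM = 20
DEFAULT_PERM_ALPHA = 0.10
#: step-2 site-inclusion threshold for the two-step construction
DEFAULT_SIG_ALPHA = 0.05


@dataclass
class SurrogateSet:
    """Estimated surrogate variables: samples x n_sv, orthonormal columns."""

    n_sv: int
    sv_matrix: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.sv_matrix = np.asarray(self.sv_matrix, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.sv_matrix.shape[1] != self.n_sv:
            raise ValueError("sv_matrix column count must equal n_sv")
        if self.explained_variance.shape != (self.n_sv,):
            raise ValueError("explained_variance must have length n_sv")
        if self.n_sv > 1 and np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")
        if self.n_sv:
            gram = self.sv_matrix.T @ self.sv_matrix
            if not np.allclose(gram, np.eye(self.n_sv), atol=1e-8):
                raise ValueError("sv_matrix columns must be orthonormal to 1e-8")

    @classmethod
    def empty(cls, n_samples: int) -> "SurrogateSet":
        return cls(0, np.empty((n_samples, 0)), np.empty(0))


def _residual_matrix(M: MethylationMatrix, design: DesignSpec) -> np.ndarray:
    """Per-site residuals of M on the stated design (SV columns excluded)."""
    dm = build_design_matrix(design.without_svs())
    if len(dm.sample_ids) <= dm.n_columns:
        raise ValueError(
            f"need more samples ({len(dm.sample_ids)}) than design columns "
            f"({dm.n_columns}) to residualise"
        )
    idx = M.sample_indices(dm.sample_ids)
    Y = M.values[:, idx].T  # samples x sites
    Q, _ = np.linalg.qr(dm.X)
    resid = Y - Q @ (Q.T @ Y)
    return resid.T  # sites x samples


def _variance_explained(resid: np.ndarray) -> np.ndarray:
    d = linalg.svdvals(resid)
    total = np.sum(d**2)
    if total <= 0:
        return np.zeros_like(d)
    return d**2 / total


def estimate_num_sv(
    M: MethylationMatrix,
    design: DesignSpec,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_PERM_ALPHA,
    seed: int | np.random.Generator | None = None,
    method: str = "be",
) -> int:
    """Permutation estimate of the number of surrogate variables.

    Each of ``n_perm`` permutations independently shuffles every site's
    residuals across samples and records the variance explained by each
    singular component of the shuffled matrix. An observed component is
    significant if its variance-explained exceeds the (1 - alpha) quantile
    of its permutation null; counting is sequential and stops at the first
    non-significant component.
    """
    if method != "be":
        raise NotImplementedError(f"num-SV method {method!r} is not implemented")
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    rng = np.random.default_rng(seed)
    resid = _residual_matrix(M, design)
    observed = _variance_explained(resid)
    null = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        null[b] = _variance_explained(rng.permuted(resid, axis=1))
    threshold = np.quantile(null, 1.0 - alpha, axis=0)
    n_sv = 0
    for ve, thr in zip(observed, threshold):
        if ve > thr:
            n_sv += 1
        else:
            break
    return n_sv


def estimate_sv_twostep(
    M: MethylationMatrix,
    design: DesignSpec,
    n_sv: int,
    sig_alpha: float = DEFAULT_SIG_ALPHA,
    components: str = "leading",
    estimator: str = "two-step",
) -> SurrogateSet:
    """Two-step surrogate-variable construction.

    ``components`` selects which step-1 singular vectors seed the
    construction: ``"leading"`` (the default, largest variance) or
    ``"trailing"`` (the smallest-variance tail of the spectrum — useful only
    for studying what deliberately uninformative SVs do to a screen).
    """
    if estimator != "two-step":
        raise NotImplementedError(f"SV estimator {estimator!r} is not implemented")
    if n_sv < 0:
        raise ValueError("n_sv must be non-negative")
    n_samples = len(design.covariates)
    if n_sv == 0:
        return SurrogateSet.empty(n_samples)
    dm = build_design_matrix(design.without_svs())
    max_sv = min(M.n_sites, n_samples) - dm.n_columns
    if n_sv > max_sv:
        raise ValueError(
            f"n_sv={n_sv} exceeds min(sites, samples) - design columns = {max_sv}"
        )
    if components not in ("leading", "trailing"):
        raise ValueError("components must be 'leading' or 'trailing'")

    resid = _residual_matrix(M, design)
    _, d, Vt = np.linalg.svd(resid, full_matrices=False)
    total = np.sum(d**2)
    n_spec = np.sum(d > d[0] * 1e-12) if d.size else 0
    if components == "leading":
        chosen = np.arange(n_sv)
    else:
        chosen = np.arange(max(int(n_spec) - n_sv, 0), int(n_spec))
    explained = d[chosen] ** 2 / total if total > 0 else np.zeros(len(chosen))

    idx = M.sample_indices([str(s) for s in design.covariates.index])
    original = M.values[:, idx]
    vectors = []
    for j in chosen:
        v = Vt[j]
        sig = _sites_associated(resid, v, sig_alpha)
        if not sig.any():
            logger.warning(
                "two-step SV %d: no significantly associated sites; "
                "falling back to the residual singular vector",
                j + 1,
            )
            vectors.append(v)
            continue
        _, _, sub_vt = np.linalg.svd(original[sig], full_matrices=False)
        corrs = _abs_corr(sub_vt, v)
        vectors.append(sub_vt[int(np.argmax(corrs))])

    basis = np.column_stack(vectors)
    q, _ = np.linalg.qr(basis)
    # fix SVD sign ambiguity: largest-magnitude loading of each SV is positive
    for j in range(q.shape[1]):
        if q[np.argmax(np.abs(q[:, j])), j] < 0:
            q[:, j] = -q[:, j]
    return SurrogateSet(n_sv, q, explained)


def _sites_associated(resid: np.ndarray, v: np.ndarray, alpha: float) -> np.ndarray:
    """Mask of sites whose residuals regress significantly on the vector v."""
    n = resid.shape[1]
    vc = v - v.mean()
    denom = float(vc @ vc)
    if denom <= 0:
        return np.zeros(resid.shape[0], dtype=bool)
    rc = resid - resid.mean(axis=1, keepdims=True)
    slope = rc @ vc / denom
    rss = np.einsum("ij,ij->i", rc, rc) - slope**2 * denom
    df = n - 2
    sigma2 = np.maximum(rss / df, 1e-300)
    t = slope / np.sqrt(sigma2 / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return p < alpha


def _abs_corr(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt(np.einsum("ij,ij->i", rc, rc) * (vc @ vc))
    denom = np.maximum(denom, 1e-300)
    return np.abs(rc @ vc) / denom


def attach_svs(
    M: MethylationMatrix,
    design: DesignSpec,
    n_sv: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    perm_alpha: float = DEFAULT_PERM_ALPHA,
    sig_alpha: float = DEFAULT_SIG_ALPHA,
    components: str = "leading",
    seed: int | np.random.Generator | None = None,
) -> tuple[DesignSpec, SurrogateSet]:
    """Estimate SVs on the complete data and return the augmented design.

    ``n_sv=None`` estimates the number by permutation first; an explicit
    integer skips that step.
    """
    if n_sv is None:
        n_sv = estimate_num_sv(M, design, n_perm=n_perm, alpha=perm_alpha, seed=seed)
    svs = estimate_sv_twostep(M, design, n_sv, sig_alpha=sig_alpha, components=components)
    return design.with_svs(svs.sv_matrix if svs.n_sv else None), svs
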