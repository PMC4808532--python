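"""The three site-screening procedures and final full-data inference.

* :func:`tt_screen` — training/testing (TT) resampling selection. At each of
  ``n_iterations`` iterations the samples are randomly partitioned into a
  training set (default 2/3) and a testing set. Every site is fitted on the
  training samples; sites whose term(s) of interest are significant at
  ``alpha_train`` become candidates and are refitted from scratch on the
  testing samples; a candidate confirmed at ``alpha_test`` earns one
  selection count. A site enters the final pool when its count reaches
  ``m = ceil(cutoff_percent / 100 * n_iterations)`` (default 50 of 100).
  Final estimates for selected sites come from one fit on the complete data.
* :func:`fdr_screen` — Benjamini–Hochberg step-up on full-data p-values:
  reject the k smallest ordered p-values where p(k) <= (k/m) * alpha
  (boundary inclusive).
* :func:`bonferroni_screen` — select sites with p <= alpha / m (inclusive).

On identical p-values the Bonferroni pool is always a subset of the FDR
pool, and TT selection is monotone in the cutoff: raising ``cutoff_percent``
can only shrink the pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import (
    DesignSpec,
    MethylationMatrix,
    RankDeficientDesignError,
    SiteFit,
    build_design_matrix,
    fit_sites,
    term_pvalues,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TTOptions",
    "ScreeningResult",
    "split_train_test",
    "tt_screen",
    "fdr_screen",
    "bonferroni_screen",
    "screen_all",
]


@dataclass(frozen=True)
class TTOptions:
    """Options for the training/testing screen (defaults are the recommended ones)."""

    train_fraction: float = 2.0 / 3.0
    n_iterations: int = 100
    cutoff_percent: float = 50.0
    alpha_train: float = 0.05
    alpha_test: float = 0.05
    engine: str = "ols"
    interest_rule: str = "all"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0.0 < self.cutoff_percent <= 100.0:
            raise ValueError("cutoff_percent must be in (0, 100]")
        for name in ("alpha_train", "alpha_test"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.engine not in ("ols", "robust"):
            raise ValueError("engine must be 'ols' or 'robust'")
        if self.interest_rule not in ("all", "any"):
            raise ValueError("interest_rule must be 'all' or 'any'")

    @property
    def min_count(self) -> int:
        """Minimum number of confirming iterations, m = ceil(cutoff% x i)."""
        return math.ceil(self.cutoff_percent / 100.0 * self.n_iterations)


@dataclass
class ScreeningResult:
    """Per-site screening outcome across the three methods."""

    site_ids: list[str]
    selection_count: np.ndarray
    selected_tt: np.ndarray
    selected_fdr: np.ndarray
    selected_bonferroni: np.ndarray
    full_pvalues: pd.DataFrame            # sites x terms, complete-data fit
    final_fits: dict[str, SiteFit]        # full-data fits for selected sites
    options: TTOptions
    n_sv: int = 0

    def selected_sites(self, method: str) -> list[str]:
        mask = {
            "tt": self.selected_tt,
            "fdr": self.selected_fdr,
            "bonferroni": self.selected_bonferroni,
        }[method]
        return [s for s, keep in zip(self.site_ids, mask) if keep]

    def to_frame(self) -> pd.DataFrame:
        """Flat results table: counts, the three selection flags, full-data stats."""
        out = pd.DataFrame(
            {
                "site_id": self.site_ids,
                "selection_count": self.selection_count,
                "selected_tt": self.selected_tt.astype(int),
                "selected_fdr": self.selected_fdr.astype(int),
                "selected_bonf": self.selected_bonferroni.astype(int),
            }
        ).set_index("site_id")
        for term in self.full_pvalues.columns:
            out[f"p[{term}]"] = self.full_pvalues[term].to_numpy()
        any_fit = next(iter(self.final_fits.values()), None)
        if any_fit is not None:
            for col in any_fit.coefficients.index:
                out[f"coef[{col}]"] = [
                    self.final_fits[s].coefficients[col] if s in self.final_fits else np.nan
                    for s in self.site_ids
                ]
                out[f"se[{col}]"] = [
                    self.final_fits[s].standard_errors[col] if s in self.final_fits else np.nan
                    for s in self.site_ids
                ]
        return out


def split_train_test(
    sample_ids: Sequence[str],
    train_fraction: float,
    rng: np.random.Generator,
    min_size: int = 2,
) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive train/test partition of the samples.

    Simple random sampling without replacement, no stratification; the
    training set gets ``round(train_fraction * n)`` samples. Errors if
    either part falls below ``min_size`` (the smallest fittable group).
    """
    sample_ids = [str(s) for s in sample_ids]
    n = len(sample_ids)
    n_train = int(round(train_fraction * n))
    n_test = n - n_train
    if n_train < min_size or n_test < min_size:
        raise ValueError(
            f"split {n_train}/{n_test} of {n} samples leaves a part smaller "
            f"than the fittable minimum ({min_size})"
        )
    perm = rng.permutation(n)
    train = [sample_ids[i] for i in perm[:n_train]]
    test = [sample_ids[i] for i in perm[n_train:]]
    return train, test


def _combine_interest(pvals: pd.DataFrame, interest: Sequence[str], alpha: float, rule: str) -> np.ndarray:
    hits = np.column_stack([pvals[t].to_numpy() < alpha for t in interest])
    return hits.all(axis=1) if rule == "all" else hits.any(axis=1)


def tt_screen(
    M: MethylationMatrix,
    design: DesignSpec,
    options: TTOptions | None = None,
) -> ScreeningResult:
    """Run the training/testing screen (TT selection flags only).

    Any surrogate variables must already be attached to ``design`` — they
    are estimated once from the complete data and reused in every
    iteration, not re-estimated per split. FDR/Bonferroni flags are left
    False here; use :func:`screen_all` for the full three-method result.
    """
    options = options or TTOptions()
    n_sites = M.n_sites
    sample_ids = design.sample_ids
    counts = np.zeros(n_sites, dtype=int)
    # one master seed; independent per-iteration substreams so results do not
    # depend on execution order
    children = np.random.SeedSequence(options.seed).spawn(options.n_iterations)
    min_size = None
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        for attempt in (0, 1):
            if min_size is None:
                # design width is constant across iterations; probe once
                min_size = build_design_matrix(design).n_columns + 2
            train, test = split_train_test(
                sample_ids, options.train_fraction, rng, min_size
            )
            try:
                # validate both halves up front so a bad draw (e.g. an empty
                # categorical level) is redrawn as a whole
                build_design_matrix(design, train)
                build_design_matrix(design, test)
                p_train, _, _ = term_pvalues(
                    M, design, train, options.engine, design.interest
                )
                break
            except RankDeficientDesignError:
                if attempt:
                    raise
                logger.warning("iteration %d: rank-deficient split design; redrawing", it)
        cand = _combine_interest(p_train, design.interest, options.alpha_train, options.interest_rule)
        n_cand = int(cand.sum())
        logger.info("iteration %d: %d candidate site(s)", it, n_cand)
        if n_cand == 0:
            continue
        p_test, _, _ = term_pvalues(
            M, design, test, options.engine, design.interest, site_mask=cand
        )
        confirmed = _combine_interest(
            p_test, design.interest, options.alpha_test, options.interest_rule
        )
        counts[np.flatnonzero(cand)[confirmed]] += 1

    selected = counts >= options.min_count
    full_p, _, _ = term_pvalues(M, design, None, options.engine)
    final_fits = _final_fits(M, design, selected, options.engine)
    return ScreeningResult(
        site_ids=list(M.site_ids),
        selection_count=counts,
        selected_tt=selected,
        selected_fdr=np.zeros(n_sites, dtype=bool),
        selected_bonferroni=np.zeros(n_sites, dtype=bool),
        full_pvalues=full_p,
        final_fits=final_fits,
        options=options,
        n_sv=design.n_sv,
    )


def _final_fits(
    M: MethylationMatrix, design: DesignSpec, mask: np.ndarray, engine: str
) -> dict[str, SiteFit]:
    if not mask.any():
        return {}
    sub = MethylationMatrix(
        [s for s, keep in zip(M.site_ids, mask) if keep],
        M.sample_ids,
        M.values[mask],
    )
    return {f.site_id: f for f in fit_sites(sub, design, engine=engine)}


def _validated_pvalues(pvalues: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(dict(pvalues)) if not isinstance(pvalues, pd.Series) else pvalues.astype(float)
    if len(s) and (s.min() < 0 or s.max() > 1 or s.isna().any()):
        raise ValueError("p-values must lie in [0, 1]")
    return s


def fdr_screen(pvalues: Mapping[str, float] | pd.Series, alpha: float = 0.05) -> set[str]:
    """Benjamini–Hochberg step-up selection on full-data p-values."""
    s = _validated_pvalues(pvalues)
    if len(s) == 0:
        return set()
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    reject = multipletests(s.to_numpy(), alpha=alpha, method="fdr_bh")[0]
    return set(s.index[reject])


def bonferroni_screen(pvalues: Mapping[str, float] | pd.Series, alpha: float = 0.05) -> set[str]:
    """Bonferroni selection: p <= alpha / m, boundary inclusive."""
    s = _validated_pvalues(pvalues)
    if len(s) == 0:
        return set()
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    reject = multipletests(s.to_numpy(), alpha=alpha, method="bonferroni")[0]
    return set(s.index[reject])


def screen_all(
    M: MethylationMatrix,
    design: DesignSpec,
    options: TTOptions | None = None,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Run all three screens on the same data and design.

    The comparators use the complete-data per-term p-values (surrogate
    variables included, same engine). With several terms of interest the
    per-term FDR/Bonferroni pools are combined under the same
    ``interest_rule`` as the TT gates.
    """
    options = options or TTOptions()
    result = tt_screen(M, design, options)
    sets_fdr = [fdr_screen(result.full_pvalues[t], alpha) for t in design.interest]
    sets_bon = [bonferroni_screen(result.full_pvalues[t], alpha) for t in design.interest]
    combine = set.intersection if options.interest_rule == "all" else set.union
    fdr_sel = combine(*sets_fdr)
    bon_sel = combine(*sets_bon)
    result.selected_fdr = np.array([s in fdr_sel for s in result.site_ids])
    result.selected_bonferroni = np.array([s in bon_sel for s in result.site_ids])
    any_selected = result.selected_tt | result.selected_fdr | result.selected_bonferroni
    missing = any_selected & ~result.selected_tt
    if missing.any():
        extra = _final_fits(M, design, missing, options.engine)
        result.final_fits.update(extra)
    return result
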