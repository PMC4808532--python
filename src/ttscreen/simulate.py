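"""Synthetic methylation studies and Monte-Carlo evaluation of the screens.

The generator builds a panel of 2,000 CpG sites across ``n`` subjects. Among
them ``k`` sites are truly important: 90% of those depend on a continuous
exposure ``x1`` (normal, mean 1, variance 1), a four-level categorical
covariate ``x2`` (multinomial with probabilities 0.15/0.25/0.25/0.35), their
interaction, and five unobserved latent variables; the remaining 10% drop
the ``x2`` main effect but keep ``x1``, the interaction and the latents.
Every unimportant site carries only latent structure plus noise. Errors are
either normal with variance 1.5 or chi-squared with one degree of freedom.
A variant draws (x1, latents) jointly with correlation 0.7^|i-j| to study
confounding between the observed exposure and the hidden structure.

Screens are judged on whether they recover the truly important sites:
sensitivity (true positives / k), specificity (true negatives / (sites - k))
and the number of incorrect selections (false positives + false negatives),
averaged over Monte-Carlo replicates.

Effect sizes are not part of the study definition and are free parameters
here; see ``docs/methods.md`` for how the defaults were chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import DesignSpec, MethylationMatrix
from .screen import TTOptions, screen_all
from .sva import attach_svs

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimMetrics",
    "simulate_dataset",
    "evaluate_selection",
    "run_replicate",
    "run_mc_study",
    "cutoff_sweep",
]

X2_LEVELS = (1, 2, 3, 4)
X2_PROBS = (0.15, 0.25, 0.25, 0.35)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic methylation study."""

    n_sites: int = 2000
    n_samples: int = 600
    k: int = 10
    error_dist: str = "normal"      # "normal" (variance error_var) or "chisq" (df=chisq_df)
    error_var: float = 1.5
    chisq_df: int = 1
    center_errors: bool = False     # chi-squared errors are used as drawn by default
    frac_both: float = 0.9
    n_latent: int = 5
    latent_correlated: bool = False
    latent_corr_base: float = 0.7
    effect_x1: float = 0.95
    effect_x2: float = 0.95
    effect_interaction: float = 0.95
    latent_loading_sd: float = 2.0
    include_sva: bool = True
    n_sv: int | None = None          # None: estimate by permutation per replicate
    sv_components: str = "leading"   # "trailing" studies deliberately uninformative SVs
    n_perm: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k > self.n_sites:
            raise ValueError("k cannot exceed n_sites")
        if not 0.0 <= self.frac_both <= 1.0:
            raise ValueError("frac_both must be in [0, 1]")
        if self.error_dist not in ("normal", "chisq"):
            raise ValueError("error_dist must be 'normal' or 'chisq'")
        if self.error_var <= 0:
            raise ValueError("error_var must be positive")
        if self.n_latent < 0:
            raise ValueError("n_latent must be non-negative")
        if self.sv_components not in ("leading", "trailing"):
            raise ValueError("sv_components must be 'leading' or 'trailing'")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    important_sites: np.ndarray      # indices, sorted
    both_sites: np.ndarray           # important sites with an x2 main effect
    x1_only_sites: np.ndarray        # important sites without the x2 main effect
    latent: np.ndarray               # n_samples x n_latent
    loadings: np.ndarray             # n_sites x n_latent
    covariates: pd.DataFrame

    @property
    def k(self) -> int:
        return len(self.important_sites)


@dataclass(frozen=True)
class SimMetrics:
    """Selection quality against the ground truth."""

    sensitivity: float
    specificity: float
    n_incorrect: int


def _draw_covariates_and_latent(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = cfg.n_samples
    if cfg.latent_correlated and cfg.n_latent > 0:
        # joint Gaussian with corr 0.7^|i-j| over (x1, L1..Lm); all marginals
        # are standard normal so the Gaussian copula is just a linear map,
        # and x1 is shifted to mean 1 afterwards.
        m = cfg.n_latent + 1
        idx = np.arange(m)
        corr = cfg.latent_corr_base ** np.abs(idx[:, None] - idx[None, :])
        z = rng.standard_normal((n, m)) @ np.linalg.cholesky(corr).T
        x1 = 1.0 + z[:, 0]
        latent = z[:, 1:]
    else:
        x1 = rng.normal(1.0, 1.0, n)
        latent = rng.standard_normal((n, cfg.n_latent))
    x2 = rng.choice(np.array(X2_LEVELS), size=n, p=np.array(X2_PROBS))
    return x1, x2, latent


def simulate_dataset(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[MethylationMatrix, pd.DataFrame, SimTruth]:
    """Generate one synthetic study: M-value panel, covariate table, truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_sites
    x1, x2, latent = _draw_covariates_and_latent(cfg, rng)
    loadings = rng.normal(0.0, cfg.latent_loading_sd, (g, cfg.n_latent))

    if cfg.error_dist == "normal":
        errors = rng.normal(0.0, math.sqrt(cfg.error_var), (g, n))
    else:
        errors = rng.chisquare(cfg.chisq_df, (g, n))
        if cfg.center_errors:
            errors -= cfg.chisq_df

    important = np.sort(rng.choice(g, size=cfg.k, replace=False))
    n_both = int(round(cfg.frac_both * cfg.k))
    shuffled = rng.permutation(important)
    both = np.sort(shuffled[:n_both])
    x1_only = np.sort(shuffled[n_both:])

    Y = loadings @ latent.T + errors
    # reference-coded signal: one coefficient per non-reference x2 level and
    # per x1-by-level interaction column
    level_ind = {lv: (x2 == lv).astype(float) for lv in X2_LEVELS[1:]}
    x2_signal = cfg.effect_x2 * sum(level_ind.values())
    inter_signal = cfg.effect_interaction * x1 * sum(level_ind.values())
    Y[important] += cfg.effect_x1 * x1 + inter_signal
    Y[both] += x2_signal

    width = len(str(max(g, n)))
    site_ids = [f"cg{i:0{width}d}" for i in range(g)]
    sample_ids = [f"s{i:0{width}d}" for i in range(n)]
    M = MethylationMatrix(site_ids, sample_ids, Y)
    covariates = pd.DataFrame(
        {"x1": x1, "x2": pd.Categorical(x2, categories=list(X2_LEVELS))},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimTruth(important, both, x1_only, latent, loadings, covariates)
    return M, covariates, truth


def default_design(M: MethylationMatrix, covariates: pd.DataFrame) -> DesignSpec:
    """The study's regression model: x1 + x2 + x1:x2, interaction of interest."""
    return DesignSpec(covariates, ["x1", "x2", "x1:x2"], ["x1:x2"])


def evaluate_selection(
    selected: Iterable[int] | Iterable[str],
    truth: SimTruth,
    n_sites: int,
    site_ids: Sequence[str] | None = None,
) -> SimMetrics:
    """Score a selected site set against the ground truth.

    ``selected`` may contain integer site indices, or site-id strings if
    ``site_ids`` is given.
    """
    selected = list(selected)
    if selected and isinstance(selected[0], str):
        if site_ids is None:
            raise ValueError("site_ids required to score string site ids")
        pos = {s: i for i, s in enumerate(site_ids)}
        selected = [pos[s] for s in selected]
    sel = set(int(i) for i in selected)
    if sel and (min(sel) < 0 or max(sel) >= n_sites):
        raise ValueError("selected indices out of range")
    important = set(int(i) for i in truth.important_sites)
    k = len(important)
    tp = len(sel & important)
    fp = len(sel - important)
    fn = k - tp
    tn = n_sites - k - fp
    sensitivity = tp / k if k else 1.0
    specificity = tn / (n_sites - k) if n_sites > k else 1.0
    return SimMetrics(sensitivity, specificity, fp + fn)


def run_replicate(
    cfg: SimConfig,
    tt_options: TTOptions | None = None,
    methods: Sequence[str] = ("tt", "fdr", "bonferroni"),
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
) -> dict:
    """One Monte-Carlo replicate: generate, (optionally) estimate SVs, screen.

    Returns a dict with the per-method :class:`SimMetrics`, the TT selection
    counts (for cutoff sweeps), the estimated number of SVs, and the truth.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gen_ss, sva_ss, tt_ss = ss.spawn(3)
    rng = np.random.default_rng(gen_ss)
    M, covariates, truth = simulate_dataset(cfg, rng)
    design = default_design(M, covariates)
    n_sv = 0
    if cfg.include_sva:
        design, svs = attach_svs(
            M,
            design,
            n_sv=cfg.n_sv,
            n_perm=cfg.n_perm,
            components=cfg.sv_components,
            seed=np.random.default_rng(sva_ss),
        )
        n_sv = svs.n_sv
    tt_options = tt_options or TTOptions()
    tt_options = replace(tt_options, seed=int(tt_ss.generate_state(1)[0] >> 1))
    result = screen_all(M, design, tt_options, alpha=alpha)
    metrics = {}
    for method in methods:
        selected = result.selected_sites(method)
        metrics[method] = evaluate_selection(selected, truth, cfg.n_sites, M.site_ids)
    return {
        "metrics": metrics,
        "selection_count": result.selection_count,
        "n_sv": n_sv,
        "truth": truth,
        "result": result,
    }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def run_mc_study(
    cfg: SimConfig,
    n_replicates: int = 100,
    methods: Sequence[str] = ("tt", "fdr", "bonferroni"),
    tt_options: TTOptions | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo summary of the screens under one simulation setting.

    Every replicate regenerates the data, re-estimates the surrogate
    variables (when enabled) and runs all requested screens on the same
    replicate data. Returns ``(summary, detail)``: the summary has one row
    per method with the mean number of incorrect selections (rounded to the
    nearest integer, half away from zero), mean sensitivity and mean
    specificity; the detail table has one row per (replicate, method).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for r, child in enumerate(children):
        rep = run_replicate(cfg, tt_options, methods, alpha, seed=child)
        for method in methods:
            m = rep["metrics"][method]
            rows.append(
                {
                    "replicate": r,
                    "method": method,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "n_incorrect": m.n_incorrect,
                    "n_sv": rep["n_sv"],
                }
            )
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby("method", sort=False)
        .agg(
            n_incorrect=("n_incorrect", "mean"),
            sensitivity=("sensitivity", "mean"),
            specificity=("specificity", "mean"),
        )
        .loc[list(methods)]
    )
    summary["n_incorrect"] = summary["n_incorrect"].map(_round_half_away)
    return summary, detail


def cutoff_sweep(
    cfg: SimConfig,
    cutoffs: Sequence[float] = tuple(range(30, 91, 10)),
    tt_options: TTOptions | None = None,
    n_replicates: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean number of incorrect TT selections as a function of the cutoff.

    The significance gates do not depend on the cutoff, so each replicate is
    screened once and every cutoff is applied to the same selection counts —
    numerically identical to rerunning the whole study per cutoff, at a
    fraction of the cost.
    """
    tt_options = tt_options or TTOptions()
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    per_cutoff = {float(c): [] for c in cutoffs}
    sens_per_cutoff = {float(c): [] for c in cutoffs}
    for child in children:
        rep = run_replicate(cfg, tt_options, methods=("tt",), seed=child)
        counts = rep["selection_count"]
        truth = rep["truth"]
        for c in cutoffs:
            m = math.ceil(float(c) / 100.0 * tt_options.n_iterations)
            selected = np.flatnonzero(counts >= m)
            metrics = evaluate_selection(selected, truth, cfg.n_sites)
            per_cutoff[float(c)].append(metrics.n_incorrect)
            sens_per_cutoff[float(c)].append(metrics.sensitivity)
    return pd.DataFrame(
        {
            "cutoff_percent": [float(c) for c in cutoffs],
            "mean_n_incorrect": [float(np.mean(per_cutoff[float(c)])) for c in cutoffs],
            "mean_sensitivity": [float(np.mean(sens_per_cutoff[float(c)])) for c in cutoffs],
        }
    ).set_index("cutoff_percent")
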