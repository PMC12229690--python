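"""Simulation benchmark: compare phylogenetically informed prediction with
OLS and PGLS predictive equations across replicated birth-death trees.

A scenario bundles tree-simulation settings, trait correlations, a
missing-data scheme and replicate count.  Each replicate simulates a tree,
optionally down-samples it to a fixed total tip count, rescales its total
branch length to 1, simulates correlated Brownian traits (one dataset per
correlation, on the same tree), withholds the dependent trait for the scheme's
taxa, fits OLS and ML-lambda PGLS on the observed taxa, and predicts every
withheld taxon with all three methods.  Everything is driven by a single root
seed through spawned child seeds, so runs are exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import tree as tree_mod
from .pgls import DesignSpec, fit_ols, fit_pgls_ml_lambda
from .predict import predict_equation, predict_phylo_informed, target_from_tree
from .simulate import (
    MissingScheme,
    SimulationFailure,
    TraitSimConfig,
    TreeSimConfig,
    downsample_taxa,
    simulate_bm_traits,
    simulate_tree,
)
from .tree import (
    Phylogeny,
    balanced_tree,
    pectinate_tree,
    shape_metrics,
    standardize_height,
    standardize_total_length,
    transform_kappa,
    vcv,
)

logger = logging.getLogger(__name__)

METHODS = ("ols_equation", "pgls_equation", "phylo_informed")
EQUATION_METHODS = ("ols_equation", "pgls_equation")


@dataclass
class ScenarioConfig:
    """One benchmark scenario.

    ``standardize`` chooses the rescaling applied before trait simulation:
    ``total_length`` (default; total branch length 1), ``height`` (root-to-tip
    height 1) or ``none``.  ``transform="kappa0"`` applies Pagel's kappa = 0
    (all branches length 1) to the tree used for fitting and prediction while
    traits stay simulated on the untransformed tree.  ``fixed_tree`` replaces
    the stochastic tree by a deterministic end-member shape (``balanced`` or
    ``pectinate``); replicates then vary only in the simulated traits.
    """

    name: str = "scenario"
    tree: TreeSimConfig = field(default_factory=TreeSimConfig)
    r_values: tuple[float, ...] = (0.25, 0.5, 0.75)
    reps: int = 1000
    missing: MissingScheme = field(
        default_factory=lambda: MissingScheme("random_fraction", 0.10)
    )
    n_taxa_total: int | None = None
    transform: str = "none"  # none | kappa0
    standardize: str = "total_length"  # total_length | height | none
    fixed_tree: str | None = None  # None | balanced | pectinate
    seed: int = 0
    max_tree_tries: int = 20000

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for r in self.r_values:
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation {r} outside (-1, 1)")
        if self.transform not in ("none", "kappa0"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.standardize not in ("total_length", "height", "none"):
            raise ValueError(f"unknown standardize {self.standardize!r}")

    # -- YAML round trip ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        tree_cfg = TreeSimConfig(
            mode=raw.get("mode", "taxa"),
            n_extant=raw.get("n_extant"),
            age=raw.get("age"),
            spec_rate=raw.get("spec_rate", 1.0),
            ext_rate=raw.get("ext_rate", 0.0),
            speciation_mode=raw.get("speciation_mode", "asymmetric"),
        )
        ms = raw.get("missing_scheme", {"kind": "random_fraction", "param": 0.10})
        missing = MissingScheme(ms["kind"], ms.get("param"))
        r = raw.get("r", [0.25, 0.5, 0.75])
        if isinstance(r, (int, float)):
            r = [r]
        return cls(
            name=raw.get("name", "scenario"),
            tree=tree_cfg,
            r_values=tuple(float(v) for v in r),
            reps=int(raw.get("reps", 1000)),
            missing=missing,
            n_taxa_total=raw.get("n_taxa"),
            transform=raw.get("transform", "none"),
            standardize=raw.get("standardize", "total_length"),
            fixed_tree=raw.get("fixed_tree"),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.tree.mode,
            "n_extant": self.tree.n_extant,
            "age": self.tree.age,
            "spec_rate": self.tree.spec_rate,
            "ext_rate": self.tree.ext_rate,
            "speciation_mode": self.tree.speciation_mode,
            "r": list(self.r_values),
            "reps": self.reps,
            "missing_scheme": {"kind": self.missing.kind, "param": self.missing.param},
            "n_taxa": self.n_taxa_total,
            "transform": self.transform,
            "standardize": self.standardize,
            "fixed_tree": self.fixed_tree,
            "seed": self.seed,
        }


def load_preset(name: str) -> ScenarioConfig:
    """Load a packaged scenario preset by name (without the .yaml suffix)."""
    ref = resources.files("phylopred") / "scenarios" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        if not path.exists():
            available = sorted(
                p.stem for p in path.parent.glob("*.yaml")
            )
            raise FileNotFoundError(f"no preset {name!r}; available: {available}")
        return ScenarioConfig.from_yaml(path)


@dataclass
class BenchmarkResult:
    """Long error table, per-tree shape metrics and scenario metadata."""

    errors: pd.DataFrame
    shapes: pd.DataFrame
    metadata: dict
    n_resampled: int = 0


def _make_tree(
    config: ScenarioConfig, seed: np.random.SeedSequence
) -> tuple[Phylogeny, int]:
    """Simulate (or construct) one analysis-ready tree; returns resample count."""
    if config.fixed_tree == "balanced":
        n = config.tree.n_extant or 128
        return balanced_tree(n), 0
    if config.fixed_tree == "pectinate":
        n = config.tree.n_extant or 100
        return pectinate_tree(n), 0

    tries = 0
    ss = seed
    while True:
        ss_tree, ss_down, ss_next = ss.spawn(3)
        try:
            tr = simulate_tree(config.tree, np.random.default_rng(ss_tree))
            if config.n_taxa_total is not None and tr.n_tips > config.n_taxa_total:
                tr = downsample_taxa(
                    tr, config.n_taxa_total, np.random.default_rng(ss_down)
                )
            return tr, tries
        except SimulationFailure as exc:
            tries += 1
            if tries >= config.max_tree_tries:
                raise RuntimeError(
                    f"tree simulation failed {tries} times: {exc}"
                ) from exc
            ss = ss_next


def run_scenario(
    config: ScenarioConfig,
    reps: int | None = None,
    seed: int | None = None,
    design: DesignSpec | None = None,
) -> BenchmarkResult:
    """Run one scenario end to end; fully deterministic in (config, seed)."""
    reps = reps if reps is not None else config.reps
    seed = seed if seed is not None else config.seed
    design = design or DesignSpec("y ~ x")
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(reps)

    rows: list[dict] = []
    shape_rows: list[dict] = []
    n_resampled = 0
    for rep in range(reps):
        ss_rep = rep_seeds[rep]
        # a replicate can fail after tree simulation too (e.g. a missing-data
        # scheme that leaves too few observed taxa); resample it wholesale
        for attempt in range(config.max_tree_tries):
            ss_tree, ss_traits, ss_rep = ss_rep.spawn(3)
            try:
                rep_rows, rep_shape, tries = _run_replicate(
                    config, design, rep, ss_tree, ss_traits
                )
                break
            except SimulationFailure as exc:
                logger.debug("replicate %d resampled: %s", rep, exc)
                n_resampled += 1
        else:
            raise RuntimeError(f"replicate {rep} failed {config.max_tree_tries} times")
        n_resampled += tries
        rows.extend(rep_rows)
        if rep_shape is not None:
            rep_shape["tree_id"] = rep
            shape_rows.append(rep_shape)
        if rep and rep % 50 == 0:
            logger.debug("scenario %s: replicate %d/%d", config.name, rep, reps)

    errors = pd.DataFrame(rows)
    shapes = pd.DataFrame(shape_rows)
    metadata = {
        "scenario": config.to_dict(),
        "reps": reps,
        "seed": seed,
        "variance_denominator": "n-1",
        "quantile_rule": "linear",
        "n_resampled": n_resampled,
    }
    return BenchmarkResult(errors, shapes, metadata, n_resampled)


def _run_replicate(config, design, rep, ss_tree, ss_traits):
    """One replicate: tree -> transforms -> traits per r -> fits -> predictions.

    Returns (error rows, shape-metric record or None, tree resample count).
    Raises SimulationFailure when the replicate cannot be completed and
    should be resampled under a fresh child seed.
    """
    tr, tries = _make_tree(config, ss_tree)
    if config.standardize == "total_length":
        tr = standardize_total_length(tr)
    elif config.standardize == "height":
        tr = standardize_height(tr)
    analysis_tree = transform_kappa(tr, 0.0) if config.transform == "kappa0" else tr
    cov = vcv(analysis_tree)
    terminal, _, _ = tree_mod.tree_descriptors(analysis_tree)
    shape_row = None
    try:
        sm = shape_metrics(tr, strict=True)
        shape_row = {
            "colless": sm.colless,
            "sackin": sm.sackin,
            "stemminess": sm.stemminess,
        }
    except tree_mod.TreeError:
        pass  # polytomous fixed trees have no strict Colless

    rows = []
    trait_seeds = ss_traits.spawn(2 * len(config.r_values))
    for k, r in enumerate(config.r_values):
        table = simulate_bm_traits(
            tr, TraitSimConfig(r=r), np.random.default_rng(trait_seeds[2 * k])
        )
        missing = _select_missing_resilient(
            table, tr, config.missing, trait_seeds[2 * k + 1]
        )
        obs = table.drop(index=missing)
        ols = fit_ols(obs, design)
        pgls = fit_pgls_ml_lambda(obs, design, cov.restrict(list(obs.index)))
        for m in missing:
            tgt = target_from_tree(cov, list(obs.index), m, {"x": table.loc[m, "x"]})
            actual = float(table.loc[m, "y"])
            preds = {
                "ols_equation": predict_equation(ols, tgt, mode="ols"),
                "pgls_equation": predict_equation(pgls, tgt, mode="pgls_generic"),
                "phylo_informed": predict_phylo_informed(pgls, tgt),
            }
            for method, res in preds.items():
                rows.append(
                    {
                        "tree_id": rep,
                        "r": r,
                        "taxon": m,
                        "method": method,
                        "actual": actual,
                        "predicted": res.point,
                        "error": actual - res.point,
                        "abs_error": abs(actual - res.point),
                        "pi_low": res.lower,
                        "pi_high": res.upper,
                        "terminal_branch_length": terminal[m],
                        "lambda_used": pgls.lam,
                    }
                )
    return rows, shape_row, tries


def _select_missing_resilient(table, tr, scheme, seed):
    from .simulate import select_missing

    missing = select_missing(table, tr, scheme, np.random.default_rng(seed))
    if not missing:
        raise SimulationFailure("missing-data scheme selected no taxa")
    if len(missing) >= len(table) - 3:
        raise SimulationFailure("too few observed taxa left to fit")
    return missing


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def error_summaries(result: BenchmarkResult) -> pd.DataFrame:
    """Pooled sample variance (n-1) and median per (r, method), plus the fold
    performance of each predictive equation relative to the phylogenetically
    informed errors."""
    if result.errors.empty:
        raise ValueError("empty benchmark result")
    recs = []
    for (r, method), grp in result.errors.groupby(["r", "method"]):
        e = grp["error"].to_numpy()
        recs.append(
            {
                "r": r,
                "method": method,
                "n": len(e),
                "sigma2": float(np.var(e, ddof=1)) if len(e) > 1 else math.nan,
                "median": float(np.median(e)),
            }
        )
    summary = pd.DataFrame(recs)
    folds = []
    for r, grp in summary.groupby("r"):
        s = grp.set_index("method")["sigma2"]
        phylo = s.get("phylo_informed", math.nan)
        for eq in EQUATION_METHODS:
            if eq in s.index:
                if phylo == 0:
                    logger.warning("zero phylo error variance; fold undefined")
                    fold = math.nan
                else:
                    fold = float(s[eq] / phylo)
                folds.append({"r": r, "method": eq, "fold_vs_phylo": fold})
    return summary.merge(pd.DataFrame(folds), on=["r", "method"], how="left")


def error_difference_tests(result: BenchmarkResult) -> pd.DataFrame:
    """One-sample t-tests on per-tree median error differences.

    For each tree the median over predicted taxa of
    ``|equation error| - |phylo error|`` is taken; a positive median means the
    phylogenetically informed prediction was the more accurate on that tree.
    """
    out = []
    df = result.errors
    for r, grp in df.groupby("r"):
        wide = grp.pivot_table(
            index=["tree_id", "taxon"], columns="method", values="abs_error"
        )
        if "phylo_informed" not in wide.columns:
            raise ValueError("result lacks phylogenetically informed errors")
        for eq in (m for m in EQUATION_METHODS if m in wide.columns):
            diffs = (
                (wide[eq] - wide["phylo_informed"])
                .groupby(level="tree_id")
                .median()
                .to_numpy()
            )
            rec = {
                "r": r,
                "method": eq,
                "n_trees": len(diffs),
                "estimate": float(np.mean(diffs)),
                "prop_positive": float(np.mean(diffs > 0)),
            }
            if len(diffs) >= 2 and np.std(diffs, ddof=1) > 0:
                t, p = stats.ttest_1samp(diffs, 0.0)
                rec["t"] = float(t)
                rec["p"] = float(p)
            else:
                logger.warning("t-test skipped: fewer than 2 trees or zero spread")
                rec["t"] = math.nan
                rec["p"] = math.nan
            out.append(rec)
    return pd.DataFrame(out)


def shape_regressions(
    result: BenchmarkResult, method: str = "phylo_informed"
) -> pd.DataFrame:
    """OLS of per-tree median absolute error on each tree-shape metric."""
    import statsmodels.api as sm

    if result.shapes.empty:
        raise ValueError("no shape metrics recorded")
    med = (
        result.errors[result.errors["method"] == method]
        .groupby(["r", "tree_id"])["abs_error"]
        .median()
        .rename("med_abs_error")
        .reset_index()
    )
    merged = med.merge(result.shapes, on="tree_id")
    out = []
    for r, grp in merged.groupby("r"):
        for metric in ("colless", "sackin", "stemminess"):
            x = grp[metric].to_numpy(float)
            if np.std(x) == 0 or np.any(~np.isfinite(x)):
                logger.warning("metric %s constant or undefined; skipped", metric)
                continue
            X = sm.add_constant(x)
            fit = sm.OLS(grp["med_abs_error"].to_numpy(), X).fit()
            out.append(
                {
                    "r": r,
                    "method": method,
                    "metric": metric,
                    "slope": float(fit.params[1]),
                    "p": float(fit.pvalues[1]),
                    "r2_adj": float(fit.rsquared_adj),
                    "n_trees": int(fit.nobs),
                }
            )
    return pd.DataFrame(
        out, columns=["r", "method", "metric", "slope", "p", "r2_adj", "n_trees"]
    )
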