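"""Benchmark input generators: birth-death trees, correlated Brownian traits,
and missing-data masks.

Trees are grown by sampling per-lineage waiting times to speciation and
extinction from exponential distributions (a Bellman-Harris style branching
process).  Two speciation modes are supported:

* ``symmetric`` (cladogenetic): at a speciation both daughters draw fresh
  speciation *and* extinction clocks.
* ``asymmetric`` (budding): one daughter continues the mother lineage — it
  keeps the mother's remaining extinction clock and draws only a fresh
  speciation clock — while the other daughter draws both afresh.

With exponential waits and no extinction the two modes coincide (a Yule
process); with extinction, inherited clocks under budding make old lineages
die sooner and trees markedly less balanced.

Traits evolve by bivariate Brownian motion: each branch of length ``b``
contributes a mean-zero bivariate normal increment with covariance ``R * b``
where ``R`` has unit rates and off-diagonal ``r``, the evolutionary
correlation between the two traits.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .tree import Phylogeny, prune_to_taxa

__all__ = [
    "TreeSimConfig",
    "TraitSimConfig",
    "SimulationFailure",
    "simulate_tree",
    "downsample_taxa",
    "simulate_bm_traits",
    "select_missing",
    "MissingScheme",
]


class SimulationFailure(RuntimeError):
    """The stopping rule could not be met (e.g. the whole tree went extinct).

    Callers are expected to resample with a fresh child seed.
    """


@dataclass
class TreeSimConfig:
    """Birth-death simulation settings.

    ``mode`` is ``"taxa"`` (run until ``n_extant`` living lineages exist; the
    tree ends just before the speciation that would create lineage
    ``n_extant + 1``) or ``"age"`` (run for a fixed duration).  The numeric
    rates are exponential *rate* parameters (mean waiting time ``1/rate``);
    an extinction rate of 0 disables extinction and, in ``taxa`` mode, yields
    an ultrametric tree.
    """

    mode: str = "taxa"
    n_extant: int | None = 100
    age: float | None = None
    spec_rate: float = 1.0
    ext_rate: float = 0.0
    speciation_mode: str = "asymmetric"
    waiting_family: str = "exponential"
    max_events: int = 500_000

    def __post_init__(self) -> None:
        if self.mode not in ("taxa", "age"):
            raise ValueError(f"mode must be 'taxa' or 'age', got {self.mode!r}")
        if self.waiting_family != "exponential":
            raise ValueError("only exponential waiting times are implemented")
        if self.speciation_mode not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown speciation_mode {self.speciation_mode!r}")
        if self.spec_rate <= 0 or self.ext_rate < 0:
            raise ValueError("need spec_rate > 0 and ext_rate >= 0")
        if self.mode == "taxa":
            if self.n_extant is None or self.n_extant < 2:
                raise ValueError("taxa mode needs n_extant >= 2")
        else:
            if self.age is None or self.age <= 0:
                raise ValueError("age mode needs age > 0")


@dataclass
class TraitSimConfig:
    """Bivariate Brownian-motion settings.

    ``r`` is the per-unit-time correlation between the traits' increments;
    rates are the diagonal of the 2x2 evolutionary rate matrix ``R``.
    """

    r: float = 0.5
    rate_x: float = 1.0
    rate_y: float = 1.0
    root_x: float = 0.0
    root_y: float = 0.0

    def rate_matrix(self) -> np.ndarray:
        if not -1.0 < self.r < 1.0:
            raise ValueError(f"correlation must lie in (-1, 1), got {self.r}")
        if self.rate_x <= 0 or self.rate_y <= 0:
            raise ValueError("trait rates must be positive")
        c = self.r * math.sqrt(self.rate_x * self.rate_y)
        R = np.array([[self.rate_x, c], [c, self.rate_y]])
        # positive definite by construction for |r| < 1
        return R


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node", "birth", "t_spec", "t_ext", "serial")

    def __init__(self, node, birth, t_spec, t_ext, serial):
        self.node = node
        self.birth = birth
        self.t_spec = t_spec
        self.t_ext = t_ext
        self.serial = serial


def _exp_wait(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


def simulate_tree(
    config: TreeSimConfig, rng: np.random.Generator | int
) -> Phylogeny:
    """Grow one birth-death tree; extinct lineages are kept as shallow tips.

    Raises :class:`SimulationFailure` if every lineage dies before the
    stopping rule is met or the event cap is exceeded.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    taxon_namespace = dendropy.TaxonNamespace()
    root = dendropy.Node()
    serial = 0

    def fresh(node, birth):
        nonlocal serial
        serial += 1
        return _Lineage(
            node,
            birth,
            birth + _exp_wait(rng, config.spec_rate),
            birth + _exp_wait(rng, config.ext_rate),
            serial,
        )

    heap: list[tuple[float, int, _Lineage]] = []

    def push(lin: _Lineage) -> None:
        heapq.heappush(heap, (min(lin.t_spec, lin.t_ext), lin.serial, lin))

    live: dict[int, _Lineage] = {}  # serial -> lineage, insertion-ordered
    tips: list[tuple[int, dendropy.Node, float, float]] = []  # (serial, node, birth, death)
    first = fresh(root, 0.0)
    live[first.serial] = first
    push(first)

    present: float | None = None
    events = 0
    while heap:
        t, _, lin = heapq.heappop(heap)
        if lin.serial not in live:
            continue
        events += 1
        if events > config.max_events:
            raise SimulationFailure("event cap exceeded before stopping rule")
        if config.mode == "age" and t >= config.age:
            present = config.age
            break
        is_speciation = lin.t_spec <= lin.t_ext
        if is_speciation:
            if config.mode == "taxa" and len(live) >= config.n_extant:
                present = t  # stop just before the (n+1)-th lineage appears
                break
            # execute the split
            del live[lin.serial]
            node = lin.node
            node.edge.length = t - lin.birth if node.parent_node else None
            left = dendropy.Node()
            right = dendropy.Node()
            node.add_child(left)
            node.add_child(right)
            if config.speciation_mode == "symmetric":
                d1 = fresh(left, t)
            else:  # budding: left continues the mother, keeps her death clock
                serial += 1
                d1 = _Lineage(
                    left, t, t + _exp_wait(rng, config.spec_rate), lin.t_ext, serial
                )
            d2 = fresh(right, t)
            live[d1.serial] = d1
            live[d2.serial] = d2
            push(d1)
            push(d2)
        else:
            del live[lin.serial]
            tips.append((lin.serial, lin.node, lin.birth, t))
            if not live:
                raise SimulationFailure("all lineages went extinct")
    else:
        present = config.age if config.mode == "age" else None

    if present is None:
        raise SimulationFailure("stopping rule never reached")
    if config.mode == "age" and len(live) == 0:
        raise SimulationFailure("no extant lineages at the target age")

    for lin in live.values():
        tips.append((lin.serial, lin.node, lin.birth, present))

    if len(tips) < 2:
        raise SimulationFailure("degenerate single-tip tree")

    # finalize edges and label tips in birth order (serials break ties)
    tips.sort(key=lambda rec: (rec[2], rec[0]))
    for i, (_, node, birth, death) in enumerate(tips):
        node.edge.length = death - birth if node.parent_node is not None else None
        taxon = dendropy.Taxon(label=f"t{i+1}")
        taxon_namespace.add_taxon(taxon)
        node.taxon = taxon

    dtree = dendropy.Tree(taxon_namespace=taxon_namespace)
    dtree.seed_node = root
    dtree.is_rooted = True
    # drop a possible unifurcation at the root (root lineage speciated once)
    while len(root.child_nodes()) == 1 and not root.is_leaf():
        (child,) = root.child_nodes()
        dtree.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    return Phylogeny(dtree)


def downsample_taxa(
    tree: Phylogeny, n_total: int, rng: np.random.Generator | int
) -> Phylogeny:
    """Keep a uniformly random subset of ``n_total`` tips (extant and extinct
    alike); pruning preserves the covariances among survivors."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = tree.tip_labels
    if n_total > len(labels):
        raise ValueError(f"cannot downsample {len(labels)} tips to {n_total}")
    keep = sorted(rng.choice(labels, size=n_total, replace=False).tolist())
    return prune_to_taxa(tree, keep)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_bm_traits(
    tree: Phylogeny, config: TraitSimConfig, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Simulate two correlated traits by Brownian motion along the tree.

    Returns a trait table indexed by taxon with columns ``x``, ``y``,
    ``y_observed`` (initially all True) and ``extant``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tree._require_lengths()
    R = config.rate_matrix()
    L = np.linalg.cholesky(R)
    root_state = np.array([config.root_x, config.root_y])

    states: dict[dendropy.Node, np.ndarray] = {}
    root = tree.dtree.seed_node
    rows: dict[str, np.ndarray] = {}
    for node in tree.dtree.preorder_node_iter():
        if node is root:
            states[node] = root_state
        else:
            b = node.edge.length
            incr = L @ rng.standard_normal(2) * math.sqrt(b) if b > 0 else 0.0
            states[node] = states[node.parent_node] + incr
        if node.is_leaf():
            rows[node.taxon.label] = states[node]

    extant = set(tree.extant_tips())
    labels = tree.tip_labels
    table = pd.DataFrame(
        {
            "x": [rows[t][0] for t in labels],
            "y": [rows[t][1] for t in labels],
            "y_observed": True,
            "extant": [t in extant for t in labels],
        },
        index=pd.Index(labels, name="taxon"),
    )
    return table


# ---------------------------------------------------------------------------
# Missing-data masks
# ---------------------------------------------------------------------------

@dataclass
class MissingScheme:
    """Which taxa lose their dependent trait.

    kinds: ``random_fraction(f)`` — ceil(f*n) tips uniformly;
    ``extinct_only`` — every non-extant tip; ``lower_quartile(count)`` —
    ``count`` tips uniformly among those with Y at or below the first
    quartile (linear-interpolation quantile); ``fraction_of_all(f)`` —
    ceil(f*n) tips uniformly among all tips, extant and extinct.
    """

    kind: str
    param: float | int | None = None

    def __post_init__(self) -> None:
        kinds = {"random_fraction", "extinct_only", "lower_quartile", "fraction_of_all"}
        if self.kind not in kinds:
            raise ValueError(f"unknown missing scheme {self.kind!r}")
        if self.kind != "extinct_only" and self.param is None:
            raise ValueError(f"scheme {self.kind!r} needs a parameter")


def select_missing(
    table: pd.DataFrame,
    tree: Phylogeny,
    scheme: MissingScheme,
    rng: np.random.Generator | int,
) -> list[str]:
    """Choose the taxa whose dependent trait is withheld."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    taxa = list(table.index)
    n = len(taxa)

    if scheme.kind in ("random_fraction", "fraction_of_all"):
        k = math.ceil(scheme.param * n)
        if k > n:
            raise ValueError("requested more missing taxa than available")
        chosen = rng.choice(taxa, size=k, replace=False).tolist()
        return sorted(chosen)
    if scheme.kind == "extinct_only":
        return sorted(t for t in taxa if not table.loc[t, "extant"])
    # lower_quartile
    count = int(scheme.param)
    q1 = float(np.quantile(table["y"].to_numpy(), 0.25))
    eligible = [t for t in taxa if table.loc[t, "y"] <= q1]
    if count > len(eligible):
        raise ValueError(
            f"requested {count} lower-quartile taxa but only {len(eligible)} eligible"
        )
    chosen = rng.choice(eligible, size=count, replace=False).tolist()
    return sorted(chosen)
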