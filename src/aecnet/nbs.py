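"""Network-Based Statistic: supra-threshold components with permutation FWE.

Edgewise two-sample t statistics are computed for every node pair,
thresholded at a strict t-value (one-sided, per contrast direction),
and the surviving edges are grouped into connected components. Each
observed component's extent (edge count) is compared against the
permutation null distribution of the *maximal* component extent
obtained by randomly exchanging group labels and re-running the whole
pipeline, which controls the family-wise error rate:

    p_FWE(extent s) = (1 + #{perm max extent >= s}) / (1 + n_perm).

Permutations are sampled uniformly with replacement; the +1 terms
account for the observed labelling, so the smallest achievable p is
1/(n_perm + 1). For small samples an exhaustive enumeration over all
label exchanges is available as an exact oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_T_THRESHOLD = 2.7  # midpoint of the conventional strict 2.5-3.0 range
DEFAULT_N_PERM = 5000


@dataclass
class Component:
    """A connected set of supra-threshold edges."""

    edges: list  # list of (u, v), u < v
    nodes: frozenset
    extent: int
    p_fwe: float | None = None

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass
class NBSResult:
    tau: float
    direction: str
    components: list = field(default_factory=list)
    n_perm: int = 0
    null_max_extent: np.ndarray | None = None
    seed: int | None = None

    @property
    def significant(self):
        return [c for c in self.components if c.p_fwe is not None and c.p_fwe <= 0.05]


def _stack(mats) -> np.ndarray:
    a = np.asarray(mats, float)
    if a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise ValueError("expected a stack of square matrices (n_subjects, n, n)")
    return a


def _edge_t(x: np.ndarray, masks: np.ndarray, n_a: int, n_b: int, welch: bool) -> np.ndarray:
    """Two-sample t per edge for each permutation mask.

    ``x`` is (n_subjects, n_edges); ``masks`` is (n_perm, n_subjects)
    boolean, True marking group A membership. Returns (n_perm, n_edges)
    t statistics for the A − B contrast. Edges with zero variance in
    both groups yield t = 0.
    """
    m = masks.astype(float)
    s1 = m @ x
    q1 = m @ (x * x)
    s2 = x.sum(0)[None, :] - s1
    q2 = (x * x).sum(0)[None, :] - q1
    mean1, mean2 = s1 / n_a, s2 / n_b
    var1 = np.maximum(q1 - s1 * mean1, 0.0) / (n_a - 1)
    var2 = np.maximum(q2 - s2 * mean2, 0.0) / (n_b - 1)
    if welch:
        se2 = var1 / n_a + var2 / n_b
    else:
        sp2 = ((n_a - 1) * var1 + (n_b - 1) * var2) / (n_a + n_b - 2)
        se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / np.sqrt(se2)
    zero = se2 <= 0
    if zero.any():
        t[zero] = 0.0
    return t


def edgewise_t(mats_a, mats_b, welch: bool = False) -> np.ndarray:
    """Node × node matrix of two-sample t statistics (A − B).

    Pooled-variance by default (the convention of NBS toolboxes), Welch
    optionally. Edges with zero variance in both groups are set to 0
    with a warning.
    """
    a, b = _stack(mats_a), _stack(mats_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    n = a.shape[1]
    tri = np.triu_indices(n, k=1)
    x = np.concatenate([a[:, tri[0], tri[1]], b[:, tri[0], tri[1]]], axis=0)
    mask = np.zeros((1, x.shape[0]), bool)
    mask[0, : a.shape[0]] = True
    t = _edge_t(x, mask, a.shape[0], b.shape[0], welch)[0]
    if np.any(t == 0):
        n_zero = int(np.sum((x.var(axis=0) == 0)))
        if n_zero:
            warnings.warn(f"{n_zero} edge(s) with zero variance; t set to 0", stacklevel=2)
    out = np.zeros((n, n))
    out[tri] = t
    return out + out.T


def _max_component_extent(edge_idx: np.ndarray, tri_u: np.ndarray, tri_v: np.ndarray) -> int:
    """Largest connected-component edge count among surviving edges
    (union–find; fast enough to run once per permutation)."""
    if len(edge_idx) == 0:
        return 0
    parent: dict[int, int] = {}

    def find(i):
        r = i
        while parent[r] != r:
            r = parent[r]
        while parent[i] != r:
            parent[i], i = r, parent[i]
        return r

    count: dict[int, int] = {}
    for e in edge_idx:
        u, v = int(tri_u[e]), int(tri_v[e])
        for w in (u, v):
            if w not in parent:
                parent[w] = w
        ru, rv = find(u), find(v)
        if ru == rv:
            count[ru] = count.get(ru, 0) + 1
        else:
            parent[rv] = ru
            count[ru] = count.get(ru, 0) + count.pop(rv, 0) + 1
    return max(count.values())


def supra_threshold_components(
    t_matrix: np.ndarray, tau: float, direction: str = "greater"
) -> list[Component]:
    """Connected components of edges with t ≥ tau (or −t ≥ tau).

    ``direction='greater'`` tests A > B; ``'less'`` tests B > A.
    Components are returned sorted by decreasing extent.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t_matrix, float)
    s = t if direction == "greater" else -t
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    n = t.shape[0]
    tri = np.triu_indices(n, k=1)
    keep = s[tri] >= tau
    g = nx.Graph()
    g.add_edges_from(
        (int(u), int(v)) for u, v, k in zip(tri[0], tri[1], keep) if k
    )
    comps = []
    for nodes in nx.connected_components(g):
        edges = sorted(
            (min(u, v), max(u, v)) for u, v in g.subgraph(nodes).edges()
        )
        comps.append(Component(edges=edges, nodes=frozenset(nodes), extent=len(edges)))
    return sorted(comps, key=lambda c: -c.extent)


def permutation_null(
    x: np.ndarray,
    n_a: int,
    n_b: int,
    tri,
    tau: float,
    sign: float,
    n_perm: int,
    rng: np.random.Generator,
    welch: bool,
    exhaustive: bool = False,
    chunk: int = 250,
) -> np.ndarray:
    """Null distribution of the maximal component extent.

    With ``exhaustive`` every distinct assignment of ``n_a`` subjects to
    group A is enumerated instead of sampling.
    """
    n = n_a + n_b
    if exhaustive:
        masks = np.zeros((0, n), bool)
        rows = []
        for comb in combinations(range(n), n_a):
            row = np.zeros(n, bool)
            row[list(comb)] = True
            rows.append(row)
        masks_all = np.array(rows)
    else:
        masks_all = np.zeros((n_perm, n), bool)
        base = np.zeros(n, bool)
        base[:n_a] = True
        for i in range(n_perm):
            masks_all[i] = rng.permutation(base)
    out = np.empty(len(masks_all), int)
    for lo in range(0, len(masks_all), chunk):
        masks = masks_all[lo : lo + chunk]
        t = sign * _edge_t(x, masks, n_a, n_b, welch)
        for j, trow in enumerate(t):
            out[lo + j] = _max_component_extent(np.nonzero(trow >= tau)[0], tri[0], tri[1])
    return out


def nbs_test(
    mats_a,
    mats_b,
    tau: float = DEFAULT_T_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    direction: str = "greater",
    seed: int | None = 0,
    welch: bool = False,
    exhaustive: bool = False,
) -> NBSResult:
    """Run the full NBS for one contrast direction.

    Parameters
    ----------
    mats_a, mats_b : array-like, (n_subjects, n, n)
        Per-subject symmetric connectivity matrices for groups A and B.
    tau : float
        Strict edgewise t threshold.
    n_perm : int
        Number of label permutations (sampled with replacement over the
        permutation group; the identity is not forcibly included — the
        +1 correction accounts for the observed labelling).
    direction : {'greater', 'less'}
        'greater' tests A > B.
    exhaustive : bool
        Enumerate all label exchanges instead of sampling (small
        samples only); ``n_perm`` is then ignored.
    """
    a, b = _stack(mats_a), _stack(mats_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_perm < 100 and not exhaustive:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution (floor {1 / (n_perm + 1):.3f})",
            stacklevel=2,
        )
    t_obs = edgewise_t(a, b, welch=welch)
    comps = supra_threshold_components(t_obs, tau, direction)

    n = a.shape[1]
    tri = np.triu_indices(n, k=1)
    x = np.concatenate([a[:, tri[0], tri[1]], b[:, tri[0], tri[1]]], axis=0)
    rng = np.random.default_rng(seed)
    sign = 1.0 if direction == "greater" else -1.0
    null = permutation_null(
        x, a.shape[0], b.shape[0], tri, tau, sign, n_perm, rng, welch, exhaustive
    )
    for c in comps:
        c.p_fwe = float((1 + np.sum(null >= c.extent)) / (1 + len(null)))
    return NBSResult(
        tau=tau,
        direction=direction,
        components=comps,
        n_perm=len(null),
        null_max_extent=null,
        seed=seed,
    )


def run_all(
    samples: dict,
    tau: float = DEFAULT_T_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    welch: bool = False,
) -> dict:
    """NBS across every (band, window) sample and both contrast directions.

    ``samples`` maps ``(band, window)`` to ``(mats_a, mats_b)``.
    Returns ``{(band, window, direction): NBSResult}``. Derived seeds
    are deterministic in the master seed and the key order.
    """
    if not samples:
        raise ValueError(
            "empty input: provide {(band, window): (mats_a, mats_b)} samples"
        )
    ss = np.random.SeedSequence(seed)
    keys = sorted(samples, key=str)
    children = ss.spawn(2 * len(keys))
    out = {}
    for i, key in enumerate(keys):
        mats_a, mats_b = samples[key]
        for j, direction in enumerate(("greater", "less")):
            child_seed = int(children[2 * i + j].generate_state(1)[0] % (2**31))
            out[(*key, direction)] = nbs_test(
                mats_a,
                mats_b,
                tau=tau,
                n_perm=n_perm,
                direction=direction,
                seed=child_seed,
                welch=welch,
            )
    return out
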