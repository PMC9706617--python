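"""Ancestral reconstruction of per-bin niche characters on a tree.

Two reconstruction routes are provided for the binary presence character
of each environmental bin:

* **Parsimony.**  Fitch-style minimum-change reconstruction, generalized
  to polytomies and to ambiguous ("unknown") tips via unit-cost dynamic
  programming over the two states.  For each node the full set of states
  attainable in *some* most-parsimonious labeling (the MPR set) is
  reported, so ambiguity is preserved rather than resolved by an
  arbitrary acctran/deltran rule.

* **Likelihood.**  A symmetric two-state continuous-time Markov model
  with a single per-MY rate q (stay probability ``(1 + exp(-2 q t)) / 2``
  over a branch of length t).  The rate is fitted by bounded 1-D
  maximization of the pruning log-likelihood — by default one shared q
  across all bins of a variable, since per-bin fitting of a binary
  character on a few dozen tips is unstable — and marginal posterior
  state probabilities are computed per node under a uniform root prior.

Unknown tips enter parsimony as the full state set {0, 1} and the
likelihood as partials (1, 1): the standard missing-data treatment, so
unavailable conditions never force a reconstructed change.

Per-bin results are then discretized (present / absent / uncertain) and
smoothed into a contiguous niche interval per node: interior gaps
strictly between present bins are filled, mirroring the assumption that
niches are continuous intervals on each gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from phyloniche.bin_tables import ABSENT, PRESENT, UNKNOWN, BinTable
from phyloniche.data_io import Phylo

__all__ = [
    "NodeReconstruction",
    "NicheVector",
    "Mk2Fit",
    "tip_sets_from_states",
    "fitch_reconstruct",
    "mk2_loglik",
    "mk2_fit",
    "mk2_marginal",
    "states_from_reconstruction",
    "smooth_niche",
    "reconstruct_table",
]

UNCERTAIN = UNKNOWN  # same glyph "?", used for internal-node uncertainty

_BIG = np.inf

DEFAULT_ML_THRESHOLD = 0.95
DEFAULT_Q_MAX = 10.0


@dataclass
class NodeReconstruction:
    """Per-bin reconstruction results at one node.

    ``parsimony_sets`` holds per-bin frozensets over {0, 1} (MPR sets);
    ``ml_prob_present`` the marginal posterior probability of presence.
    """

    node_id: int
    parsimony_sets: list[frozenset[int]] | None = None
    ml_prob_present: np.ndarray | None = None


@dataclass
class NicheVector:
    """A node's smoothed per-bin niche with the contiguous present run."""

    states: np.ndarray                # "<U1" over bins: 1 / 0 / ?
    filled: np.ndarray                # bins relabeled present by smoothing
    interval: tuple[int, int] | None  # (first, last) present bin index

    @property
    def n_present(self) -> int:
        return int((self.states == PRESENT).sum())


@dataclass
class Mk2Fit:
    """Fitted symmetric-model rate for one character set."""

    q: float
    loglik: float
    at_lower_bound: bool = False
    at_upper_bound: bool = False


def tip_sets_from_states(states: np.ndarray | list[str]) -> list[frozenset[int]]:
    """Translate ternary characters into tip state sets ({0,1} for '?')."""
    table = {PRESENT: frozenset({1}), ABSENT: frozenset({0}), UNKNOWN: frozenset({0, 1})}
    return [table[s] for s in states]


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

def fitch_reconstruct(
    phylo: Phylo,
    tip_chars: dict[str, frozenset[int] | set[int]],
) -> tuple[dict[int, frozenset[int]], int]:
    """Minimum-change reconstruction of a binary character.

    ``tip_chars`` maps tip label -> observed state set (a singleton, or
    {0, 1} for unknown).  Returns per-node MPR sets keyed by node id and
    the parsimony score (minimal number of changes).  Polytomies are
    handled exactly: the dynamic program minimizes unit-cost changes over
    all labelings, so no binarization is needed.
    """
    nodes = phylo.postorder()
    down = {}  # node_id -> array(2): min changes in subtree given node state
    for node in nodes:
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_chars:
                raise KeyError(f"tip {label!r} missing from the character map")
            obs = frozenset(tip_chars[label])
            if not obs or not obs <= {0, 1}:
                raise ValueError(f"tip {label!r}: state set {obs} invalid")
            down[node.node_id] = np.array(
                [0.0 if 0 in obs else _BIG, 0.0 if 1 in obs else _BIG]
            )
        else:
            cost = np.zeros(2)
            for child in node.child_nodes():
                c = down[child.node_id]
                # staying costs c[s]; switching costs c[other] + 1
                cost += np.minimum(c, c[::-1] + 1.0)
            down[node.node_id] = cost

    root = phylo.root
    score = float(np.min(down[root.node_id]))

    up = {root.node_id: np.zeros(2)}  # min changes outside subtree given node state
    for node in phylo.preorder():
        for child in node.child_nodes():
            sib_cost = down[node.node_id] - np.minimum(
                down[child.node_id], down[child.node_id][::-1] + 1.0
            )
            base = up[node.node_id] + sib_cost  # parent-state cost excluding child
            up[child.node_id] = np.minimum(base, base[::-1] + 1.0)

    sets: dict[int, frozenset[int]] = {}
    for node in nodes:
        total = down[node.node_id] + up[node.node_id]
        best = np.min(total)
        sets[node.node_id] = frozenset(np.flatnonzero(total <= best + 1e-9).tolist())
    return sets, int(round(score))


# ---------------------------------------------------------------------------
# Likelihood (symmetric 2-state Markov model)
# ---------------------------------------------------------------------------

def _p_stay(q: float, t: float) -> float:
    return 0.5 * (1.0 + np.exp(-2.0 * q * t))


def _down_partials(
    phylo: Phylo,
    tip_chars: dict[str, frozenset[int] | set[int]],
    q: float,
) -> tuple[dict[int, np.ndarray], float]:
    """Scaled subtree partial likelihoods; returns (partials, log scale)."""
    down: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in phylo.postorder():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_chars:
                raise KeyError(f"tip {label!r} missing from the character map")
            obs = frozenset(tip_chars[label])
            down[node.node_id] = np.array(
                [1.0 if 0 in obs else 0.0, 1.0 if 1 in obs else 0.0]
            )
        else:
            part = np.ones(2)
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                stay = _p_stay(q, t)
                c = down[child.node_id]
                part *= np.array(
                    [stay * c[0] + (1 - stay) * c[1], (1 - stay) * c[0] + stay * c[1]]
                )
            m = part.max()
            if m > 0:
                part = part / m
                log_scale += np.log(m)
            down[node.node_id] = part
    return down, log_scale


def mk2_loglik(
    phylo: Phylo,
    tip_chars: dict[str, frozenset[int] | set[int]],
    q: float,
) -> float:
    """Pruning log-likelihood of a binary character at rate q (per MY).

    Uniform (1/2, 1/2) root prior; unknown tips contribute partials
    (1, 1).  Branch lengths are in MY.
    """
    if q <= 0:
        raise ValueError("rate q must be positive")
    down, log_scale = _down_partials(phylo, tip_chars, q)
    root = down[phylo.root.node_id]
    lik = 0.5 * root[0] + 0.5 * root[1]
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def mk2_fit(
    phylo: Phylo,
    characters: list[dict[str, frozenset[int]]] | dict[str, frozenset[int]],
    q_max: float = DEFAULT_Q_MAX,
    q_min: float = 1e-8,
) -> Mk2Fit:
    """Maximum-likelihood rate for one character or shared across many.

    Passing a list of per-bin character maps fits one q maximizing the
    summed log-likelihood — the default mode for a variable's bin table.
    Bounded Brent search over log q (a rate is a scale parameter, so the
    surface is near-flat at the linear scale's right end); hitting either
    bound is flagged on the result (the lower bound simply means no
    change signal).
    """
    if phylo.n_tips < 2:
        raise ValueError("rate fitting needs a tree with at least 2 tips")
    char_list = characters if isinstance(characters, list) else [characters]
    if not char_list:
        raise ValueError("no characters to fit")

    def neg_ll_log(u: float) -> float:
        return -sum(mk2_loglik(phylo, ch, float(np.exp(u))) for ch in char_list)

    res = minimize_scalar(
        neg_ll_log, bounds=(np.log(q_min), np.log(q_max)), method="bounded",
        options={"xatol": 1e-8},
    )
    q_hat = float(np.exp(res.x))
    return Mk2Fit(
        q=q_hat,
        loglik=-float(res.fun),
        at_lower_bound=q_hat <= q_min * 1.001,
        at_upper_bound=q_hat >= q_max * 0.999,
    )


def mk2_marginal(
    phylo: Phylo,
    tip_chars: dict[str, frozenset[int] | set[int]],
    q: float,
) -> dict[int, float]:
    """Marginal posterior probability of state 1 ("present") per node.

    Combines each node's subtree partials with rest-of-tree partials
    (root prior folded in), so the two probabilities at every node sum
    to 1.  Tips with a definite state get probability 0 or 1; unknown
    tips get a genuine posterior.
    """
    if q <= 0:
        raise ValueError("rate q must be positive")
    down, _ = _down_partials(phylo, tip_chars, q)

    up: dict[int, np.ndarray] = {phylo.root.node_id: np.array([0.5, 0.5])}
    for node in phylo.preorder():
        for child in node.child_nodes():
            rest = up[node.node_id].copy()
            for sib in node.child_nodes():
                if sib is child:
                    continue
                t = sib.edge.length or 0.0
                stay = _p_stay(q, t)
                c = down[sib.node_id]
                rest *= np.array(
                    [stay * c[0] + (1 - stay) * c[1], (1 - stay) * c[0] + stay * c[1]]
                )
            t = child.edge.length or 0.0
            stay = _p_stay(q, t)
            # transpose = same matrix (symmetric)
            upc = np.array(
                [stay * rest[0] + (1 - stay) * rest[1], (1 - stay) * rest[0] + stay * rest[1]]
            )
            m = upc.max()
            up[child.node_id] = upc / m if m > 0 else upc

    out: dict[int, float] = {}
    for node in phylo.postorder():
        joint = down[node.node_id] * up[node.node_id]
        total = joint.sum()
        if total <= 0:
            raise ValueError(f"zero likelihood at node {node.node_id}")
        out[node.node_id] = float(joint[1] / total)
    return out


# ---------------------------------------------------------------------------
# Discretization and smoothing
# ---------------------------------------------------------------------------

def states_from_reconstruction(
    rec: NodeReconstruction,
    method: str = "parsimony",
    ml_threshold: float = DEFAULT_ML_THRESHOLD,
) -> np.ndarray:
    """Collapse one node's per-bin reconstruction to ternary states.

    Parsimony: present iff the MPR set is {1}, absent iff {0}, else
    uncertain.  Likelihood: present iff P >= threshold, absent iff
    P <= 1 - threshold, else uncertain.
    """
    if method == "parsimony":
        if rec.parsimony_sets is None:
            raise ValueError("reconstruction has no parsimony sets")
        out = np.empty(len(rec.parsimony_sets), dtype="<U1")
        for i, s in enumerate(rec.parsimony_sets):
            out[i] = PRESENT if s == {1} else ABSENT if s == {0} else UNCERTAIN
        return out
    if method == "likelihood":
        if rec.ml_prob_present is None:
            raise ValueError("reconstruction has no ML probabilities")
        if not 0.5 < ml_threshold < 1.0:
            raise ValueError("ml_threshold must be in (0.5, 1)")
        p = np.asarray(rec.ml_prob_present)
        out = np.full(p.shape, UNCERTAIN, dtype="<U1")
        out[p >= ml_threshold] = PRESENT
        out[p <= 1.0 - ml_threshold] = ABSENT
        return out
    raise ValueError(f"unknown method {method!r}")


def smooth_niche(bin_states: np.ndarray | list[str]) -> NicheVector:
    """Fill interior gaps so the present run is contiguous.

    Absent or uncertain bins strictly between two present bins are
    relabeled present and flagged ``filled`` — a niche is modeled as one
    continuous interval per gradient.  A vector with no present bin is
    returned as an empty niche with a warning.
    """
    states = np.asarray(bin_states, dtype="<U1").copy()
    filled = np.zeros(states.shape, dtype=bool)
    present = np.flatnonzero(states == PRESENT)
    if present.size == 0:
        warnings.warn("no present bin in reconstruction; empty niche", stacklevel=2)
        return NicheVector(states=states, filled=filled, interval=None)
    lo, hi = int(present[0]), int(present[-1])
    gap = np.arange(lo, hi + 1)[states[lo : hi + 1] != PRESENT]
    states[gap] = PRESENT
    filled[gap] = True
    return NicheVector(states=states, filled=filled, interval=(lo, hi))


# ---------------------------------------------------------------------------
# Whole-table reconstruction
# ---------------------------------------------------------------------------

def reconstruct_table(
    phylo: Phylo,
    table: BinTable,
    methods: tuple[str, ...] = ("parsimony", "likelihood"),
    ml_threshold: float = DEFAULT_ML_THRESHOLD,
    shared_rate: bool = True,
    q_max: float = DEFAULT_Q_MAX,
) -> tuple[dict[int, NodeReconstruction], Mk2Fit | list[Mk2Fit] | None]:
    """Reconstruct every bin of a bin table at every node.

    Returns per-node :class:`NodeReconstruction` (keyed by node id) and
    the fitted rate (a single shared :class:`Mk2Fit`, or one per bin when
    ``shared_rate`` is off; None when likelihood is not requested).
    Missing species raise via the per-bin reconstructions.
    """
    n_bins = table.scheme.n_bins
    per_bin_chars: list[dict[str, frozenset[int]]] = []
    for b in range(n_bins):
        per_bin_chars.append(
            {sp: tip_sets_from_states([table.rows[sp][b]])[0] for sp in table.rows}
        )

    recs = {
        n.node_id: NodeReconstruction(node_id=n.node_id)
        for n in phylo.postorder()
    }

    if "parsimony" in methods:
        for r in recs.values():
            r.parsimony_sets = [frozenset()] * n_bins
        for b, chars in enumerate(per_bin_chars):
            sets, _score = fitch_reconstruct(phylo, chars)
            for node_id, s in sets.items():
                recs[node_id].parsimony_sets[b] = s

    fit: Mk2Fit | list[Mk2Fit] | None = None
    if "likelihood" in methods:
        for r in recs.values():
            r.ml_prob_present = np.empty(n_bins)
        if shared_rate:
            fit = mk2_fit(phylo, per_bin_chars, q_max=q_max)
            rates = [fit.q] * n_bins
        else:
            fit = [mk2_fit(phylo, chars, q_max=q_max) for chars in per_bin_chars]
            rates = [f.q for f in fit]
        for b, chars in enumerate(per_bin_chars):
            marg = mk2_marginal(phylo, chars, rates[b])
            for node_id, p in marg.items():
                recs[node_id].ml_prob_present[b] = p
    return recs, fit
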