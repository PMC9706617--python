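"""Niche change along branches: detection, dating, classes, projection.

Comparing a parent's and a child's reconstructed niche bin-by-bin yields
per-branch events: a bin switching absent -> present is an *expansion*,
present -> absent a *retraction*; identical definite states are stasis
and any uncertain endpoint leaves the bin ambiguous.  Events are dated
only to the branch's time interval (parent age, child age) on the
ultrametric tree — no placement within a branch is claimed.

Reconstructed niches are also summarized qualitatively: position of the
niche midpoint relative to the scheme midpoint gives warm/cold (or
wet/dry for humidity variables), and the present-bin count relative to
the median across extant species gives broad/narrow.

When the input tree carries several accessions per species, the
analysis is replicated over random single-representative prunings and
combined by per-node majority rule, matching nodes across replicate
trees by their descendant-species sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from phyloniche.asr import NicheVector, NodeReconstruction, UNCERTAIN
from phyloniche.bin_tables import ABSENT, PRESENT, BinScheme
from phyloniche.data_io import EnvLayer, Phylo

__all__ = [
    "EXPANSION",
    "RETRACTION",
    "STASIS",
    "AMBIGUOUS",
    "BranchChange",
    "EventSummary",
    "NicheClass",
    "compare_branch",
    "summarize_events",
    "classify_niche",
    "combine_replicates",
    "project_niche",
]

EXPANSION = "EXPANSION"
RETRACTION = "RETRACTION"
STASIS = "STASIS"
AMBIGUOUS = "AMBIGUOUS"

#: fraction of the scheme span the niche midpoint must deviate from the
#: scheme midpoint to be called warm/cold (wet/dry)
DEFAULT_POSITION_THRESHOLD = 0.10

_AXIS_LABELS = {
    "temperature": ("WARM", "COLD"),
    "humidity": ("WET", "DRY"),
}


@dataclass(frozen=True)
class BranchChange:
    """One bin's classified change on one branch."""

    parent: int
    child: int
    bin_index: int
    label: str


@dataclass
class EventSummary:
    """Event counts and the dated time interval of one branch."""

    parent: int
    child: int
    parent_age: float
    child_age: float
    n_expansion: int
    n_retraction: int
    n_ambiguous: int
    n_stasis: int


@dataclass
class NicheClass:
    """Qualitative class of one node's niche on one variable."""

    node_id: int
    position: str  # WARM/COLD/INTERMEDIATE or WET/DRY/INTERMEDIATE
    breadth: str   # BROAD or NARROW


def compare_branch(
    parent: NicheVector,
    child: NicheVector,
    parent_id: int = -1,
    child_id: int = -1,
) -> list[BranchChange]:
    """Classify every bin's change between a parent and child niche."""
    if parent.states.shape != child.states.shape:
        raise ValueError("parent and child niches use different bin schemes")
    out = []
    for b, (p, c) in enumerate(zip(parent.states, child.states)):
        if p == UNCERTAIN or c == UNCERTAIN:
            label = AMBIGUOUS
        elif p == ABSENT and c == PRESENT:
            label = EXPANSION
        elif p == PRESENT and c == ABSENT:
            label = RETRACTION
        else:
            label = STASIS
        out.append(BranchChange(parent=parent_id, child=child_id, bin_index=b, label=label))
    return out


def summarize_events(
    phylo: Phylo,
    changes: list[BranchChange],
) -> list[EventSummary]:
    """Count events per branch and attach the branch's age interval."""
    ages = phylo.node_ages()
    branches: dict[tuple[int, int], dict[str, int]] = {}
    for ch in changes:
        key = (ch.parent, ch.child)
        counts = branches.setdefault(
            key, {EXPANSION: 0, RETRACTION: 0, AMBIGUOUS: 0, STASIS: 0}
        )
        counts[ch.label] += 1
    out = []
    for (parent, child), counts in sorted(branches.items()):
        out.append(
            EventSummary(
                parent=parent,
                child=child,
                parent_age=ages.get(parent, float("nan")),
                child_age=ages.get(child, float("nan")),
                n_expansion=counts[EXPANSION],
                n_retraction=counts[RETRACTION],
                n_ambiguous=counts[AMBIGUOUS],
                n_stasis=counts[STASIS],
            )
        )
    return out


def classify_niche(
    niche: NicheVector,
    scheme: BinScheme,
    breadth_reference: list[NicheVector],
    kind: str = "temperature",
    position_threshold: float = DEFAULT_POSITION_THRESHOLD,
    node_id: int = -1,
) -> NicheClass:
    """Qualitative position and breadth labels for one niche.

    Position compares the present interval's midpoint (in variable
    units) against the scheme midpoint: deviation beyond
    ``position_threshold`` x span is WARM/WET above, COLD/DRY below,
    else INTERMEDIATE.  Breadth is BROAD iff the present-bin count
    strictly exceeds the median across ``breadth_reference`` (normally
    the extant species); ties are NARROW.
    """
    if niche.interval is None:
        raise ValueError("cannot classify an empty niche")
    if kind not in _AXIS_LABELS:
        raise ValueError(f"kind must be one of {sorted(_AXIS_LABELS)}")
    hi_label, lo_label = _AXIS_LABELS[kind]
    lo_bin, hi_bin = niche.interval
    centers = scheme.centers
    midpoint = 0.5 * (centers[lo_bin] + centers[hi_bin])
    scheme_mid = 0.5 * (scheme.lo + scheme.hi)
    span = scheme.hi - scheme.lo
    dev = (midpoint - scheme_mid) / span
    if dev > position_threshold:
        position = hi_label
    elif dev < -position_threshold:
        position = lo_label
    else:
        position = "INTERMEDIATE"

    ref_counts = [nv.n_present for nv in breadth_reference if nv.interval is not None]
    if not ref_counts:
        raise ValueError("breadth_reference contains no non-empty niche")
    breadth = "BROAD" if niche.n_present > float(np.median(ref_counts)) else "NARROW"
    return NicheClass(node_id=node_id, position=position, breadth=breadth)


def combine_replicates(
    replicates: list[dict[frozenset[str], NodeReconstruction]],
    rule: str = "majority",
) -> dict[frozenset[str], NodeReconstruction]:
    """Per-node majority consensus across replicate reconstructions.

    Replicate reconstructions are keyed by each node's descendant-species
    fingerprint so nodes match across trees that differ in which
    conspecific accession was retained.  Per node and bin the consensus
    parsimony state is the state reconstructed as definite in more than
    half of the replicates that contain the node (ties and mixed signals
    stay ambiguous, i.e. {0, 1}); ML probabilities are averaged.
    Fingerprints absent from every replicate cannot occur; fingerprints
    absent from some replicates are combined over the ones that have
    them, with a warning.
    """
    if rule != "majority":
        raise ValueError(f"unknown combination rule {rule!r}")
    if not replicates:
        raise ValueError("no replicates to combine")
    all_keys: set[frozenset[str]] = set()
    for rep in replicates:
        all_keys |= set(rep)
    out: dict[frozenset[str], NodeReconstruction] = {}
    for key in all_keys:
        present_in = [rep[key] for rep in replicates if key in rep]
        if len(present_in) < len(replicates):
            warnings.warn(
                f"node with {len(key)} descendant species matched in only "
                f"{len(present_in)}/{len(replicates)} replicates",
                stacklevel=2,
            )
        rec = NodeReconstruction(node_id=-1)
        first = present_in[0]
        if first.parsimony_sets is not None:
            n_bins = len(first.parsimony_sets)
            sets: list[frozenset[int]] = []
            for b in range(n_bins):
                n = len(present_in)
                n_present = sum(1 for r in present_in if r.parsimony_sets[b] == {1})
                n_absent = sum(1 for r in present_in if r.parsimony_sets[b] == {0})
                if n_present * 2 > n:
                    sets.append(frozenset({1}))
                elif n_absent * 2 > n:
                    sets.append(frozenset({0}))
                else:
                    sets.append(frozenset({0, 1}))
            rec.parsimony_sets = sets
        if first.ml_prob_present is not None:
            rec.ml_prob_present = np.mean(
                [r.ml_prob_present for r in present_in], axis=0
            )
        out[key] = rec
    return out


def project_niche(
    niche: NicheVector,
    layer: EnvLayer,
    scheme: BinScheme,
    area_mask: np.ndarray | None = None,
    include_uncertain: bool = False,
) -> np.ndarray:
    """Geographic footprint of a niche: cells whose value is in the niche.

    A valid cell is True iff its layer value falls in a present bin
    (optionally also counting uncertain bins), and inside ``area_mask``
    when one is given.
    """
    if layer.variable_id != scheme.variable_id:
        raise ValueError(
            f"layer variable {layer.variable_id!r} does not match scheme "
            f"{scheme.variable_id!r}"
        )
    wanted = niche.states == PRESENT
    if include_uncertain:
        wanted |= niche.states == UNCERTAIN
    out = np.zeros(layer.shape, dtype=bool)
    valid = layer.valid_mask
    vals = layer.values[valid]
    in_span = (vals >= scheme.lo) & (vals <= scheme.hi)
    idx = scheme.bin_of(vals[in_span])
    hit = np.zeros(int(valid.sum()), dtype=bool)
    hit[np.flatnonzero(in_span)] = wanted[idx]
    out[valid] = hit
    if area_mask is not None:
        out &= np.asarray(area_mask, dtype=bool)
    return out
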