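"""Ternary niche character tables over uniform environmental bins.

Each environmental variable's global span (across all species'
availability envelopes, with a little padding for headroom) is divided
into uniform bins — by default 66 for temperature and 72 for humidity
variables.  Each species is then tallied per bin as:

* ``1`` (present)  — the bin overlaps the species' used range;
* ``0`` (absent)   — the bin was available inside M but unused;
* ``?`` (unknown)  — the bin's conditions were unavailable inside M, so
  absence there carries no information about the niche.

Under the default ``peripheral`` policy, unavailable bins on a given
side are only marked unknown when the species' use actually reaches the
availability limit on that side (within one bin width): a species deep
inside its available envelope demonstrably tolerates nothing beyond it.
The stricter ``all_unavailable`` policy marks every unavailable bin
unknown regardless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phyloniche.niche_profiles import NicheProfile

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "BinScheme",
    "BinTable",
    "build_bin_scheme",
    "assign_states",
    "write_bin_table",
    "read_bin_table",
    "DEFAULT_N_BINS",
]

PRESENT = "1"
ABSENT = "0"
UNKNOWN = "?"
_STATES = frozenset({PRESENT, ABSENT, UNKNOWN})

#: shipped bin counts per variable kind
DEFAULT_N_BINS = {"temperature": 66, "humidity": 72}

DEFAULT_PAD = 0.05


@dataclass(frozen=True)
class BinScheme:
    """Uniform binning of one variable's global range."""

    variable_id: str
    lo: float
    hi: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.hi > self.lo:
            raise ValueError("bin scheme span is degenerate (hi <= lo)")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + self.width / 2.0

    def bin_of(self, value: float | np.ndarray) -> np.ndarray:
        """Bin index of a value; the last bin is closed above.

        Values outside [lo, hi] clip to the end bins; callers that care
        must range-check first.
        """
        idx = np.floor((np.asarray(value, dtype=float) - self.lo) / self.width)
        return np.clip(idx, 0, self.n_bins - 1).astype(int)


@dataclass
class BinTable:
    """Species x bins matrix of ternary character states."""

    scheme: BinScheme
    rows: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, vec in self.rows.items():
            self.rows[sp] = _check_vector(sp, np.asarray(vec, dtype="<U1"), self.scheme.n_bins)

    @property
    def species(self) -> list[str]:
        return sorted(self.rows)

    def add(self, species: str, states: np.ndarray) -> None:
        self.rows[species] = _check_vector(species, np.asarray(states, dtype="<U1"), self.scheme.n_bins)


def _check_vector(species: str, vec: np.ndarray, n_bins: int) -> np.ndarray:
    if vec.shape != (n_bins,):
        raise ValueError(f"{species}: state vector length {vec.shape} != n_bins {n_bins}")
    bad = set(vec) - _STATES
    if bad:
        raise ValueError(f"{species}: invalid character state(s) {bad}")
    present = np.flatnonzero(vec == PRESENT)
    if present.size == 0:
        raise ValueError(f"{species}: no present bin")
    if not np.all(np.diff(present) == 1):
        raise ValueError(f"{species}: present bins are not contiguous")
    known = np.flatnonzero(vec != UNKNOWN)
    unknown = np.flatnonzero(vec == UNKNOWN)
    interior = unknown[(unknown > known[0]) & (unknown < known[-1])]
    if interior.size:
        raise ValueError(f"{species}: unknown state at interior bin {int(interior[0])}")
    return vec


def build_bin_scheme(
    profiles: list[NicheProfile],
    n_bins: int,
    pad: float = DEFAULT_PAD,
) -> BinScheme:
    """Global uniform bin scheme spanning all species' availability.

    The span is the union of available ranges, extended by ``pad`` x span
    on each side so reconstructed ancestral niches have headroom beyond
    any extant extreme.
    """
    if not profiles:
        raise ValueError("no profiles given")
    var = profiles[0].variable_id
    for p in profiles:
        if p.variable_id != var:
            raise ValueError(f"mixed variables in profiles: {var!r} vs {p.variable_id!r}")
    lo = min(p.available_range[0] for p in profiles)
    hi = max(p.available_range[1] for p in profiles)
    if hi <= lo:
        raise ValueError("degenerate global span (hi <= lo)")
    span = hi - lo
    return BinScheme(variable_id=var, lo=lo - pad * span, hi=hi + pad * span, n_bins=n_bins)


def assign_states(
    profile: NicheProfile,
    scheme: BinScheme,
    unknown_policy: str = "peripheral",
) -> np.ndarray:
    """Ternary character vector of one species on a bin scheme.

    A bin is present iff it overlaps the used range (bins are half-open
    ``[e_i, e_i+1)``, the last bin closed).  Non-present bins wholly
    outside the availability envelope become unknown according to
    ``unknown_policy`` (see module docstring); everything else is absent.
    """
    if profile.variable_id != scheme.variable_id:
        raise ValueError(
            f"profile variable {profile.variable_id!r} does not match scheme "
            f"{scheme.variable_id!r}"
        )
    if unknown_policy not in ("peripheral", "all_unavailable"):
        raise ValueError(f"unknown policy {unknown_policy!r}")
    ulo, uhi = profile.used_range
    alo, ahi = profile.available_range
    if ulo < scheme.lo or uhi > scheme.hi:
        raise ValueError(
            f"used range [{ulo}, {uhi}] of {profile.species} falls outside the "
            f"scheme span [{scheme.lo}, {scheme.hi}]"
        )
    edges = scheme.edges
    lower, upper = edges[:-1], edges[1:]
    vec = np.full(scheme.n_bins, ABSENT, dtype="<U1")

    # present run from the bins containing the interval endpoints; an upper
    # endpoint exactly on an edge does not reach into the next bin
    lo_bin = int(scheme.bin_of(ulo))
    hi_bin = int(scheme.bin_of(uhi))
    if uhi > ulo and hi_bin > lo_bin and uhi == edges[hi_bin]:
        hi_bin -= 1
    overlap = np.zeros(scheme.n_bins, dtype=bool)
    overlap[lo_bin : hi_bin + 1] = True
    vec[overlap] = PRESENT

    below = upper <= alo   # wholly below availability
    above = lower >= ahi   # wholly above availability
    if unknown_policy == "all_unavailable":
        unknown = below | above
    else:
        tol = scheme.width
        unknown = np.zeros(scheme.n_bins, dtype=bool)
        if ulo < alo + tol:   # use reaches the lower availability limit
            unknown |= below
        if uhi > ahi - tol:   # use reaches the upper availability limit
            unknown |= above
    unknown &= ~overlap
    vec[unknown] = UNKNOWN
    return vec


def write_bin_table(table: BinTable, path: str | Path) -> None:
    """Serialize a bin table as CSV plus a JSON metadata sidecar.

    Columns are ``species, bin_0 .. bin_{n-1}`` with literal "1"/"0"/"?"
    states; the sidecar ``<path>.meta.json`` records the scheme.
    """
    if not table.rows:
        raise ValueError("bin table has no species")
    path = Path(path)
    cols = [f"bin_{i}" for i in range(table.scheme.n_bins)]
    df = pd.DataFrame(
        [[sp, *table.rows[sp]] for sp in table.species],
        columns=["species", *cols],
    )
    df.to_csv(path, index=False)
    meta = {
        "variable_id": table.scheme.variable_id,
        "lo": table.scheme.lo,
        "hi": table.scheme.hi,
        "n_bins": table.scheme.n_bins,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_bin_table(path: str | Path) -> BinTable:
    """Read a bin table written by :func:`write_bin_table`."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    scheme = BinScheme(
        variable_id=meta["variable_id"],
        lo=float(meta["lo"]),
        hi=float(meta["hi"]),
        n_bins=int(meta["n_bins"]),
    )
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty bin table")
    cols = [f"bin_{i}" for i in range(scheme.n_bins)]
    rows: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        states = row[cols].to_numpy(dtype="<U1")
        for j, s in enumerate(states):
            if s not in _STATES:
                raise ValueError(
                    f"{path}: invalid state {s!r} at species {row['species']!r}, "
                    f"column bin_{j}"
                )
        rows[str(row["species"])] = states
    return BinTable(scheme=scheme, rows=rows)
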