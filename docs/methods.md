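# Methods

## The inference problem

Given occurrences, aligned environmental grids and a dated ultrametric
tree, the pipeline estimates each ancestor's position and breadth on each
environmental gradient and locates niche expansion/retraction events on
branches. The niche on one gradient is modeled throughout as a single
contiguous interval: gaps between a species' observed minimum and maximum
are filled, and reconstructed per-bin states are smoothed back into an
interval per node. This is a deliberate coarse-graining — it captures
range position and breadth, not multimodal structure.

## Accessible areas and the unknown state

The accessible area M of a species is the union of geodesic buffers
around its occurrences (haversine distance, Earth radius 6371.0 km, cell
membership tested at cell centers), intersected with valid grid cells;
`clip_area` applies expert masks (e.g. removing an island a species could
not reach) and refuses to drop occupied cells unless forced. M matters
because absence is only informative where presence was possible: bins
wholly outside the availability envelope are coded `?` rather than `0`.

Two policies govern the unknown coding. Under `peripheral` (default),
unavailable bins on a given side are unknown only when the species' used
range reaches the availability limit on that side within one bin width —
a species observed right up against the edge of what was available might
tolerate more; a species well inside the envelope demonstrably stops
short of it. Under `all_unavailable`, every unavailable bin is unknown.
The `peripheral` reading is the default because the conditional rule
extracts strictly more information; the stricter policy is provided since
the methodological literature is ambiguous on this point, and its unknown
set always contains the peripheral one (a tested invariant).

## Binning

Bins are uniform over the multi-species span of availability, padded 5%
per side so reconstructed ancestral extremes have headroom; defaults are
66 bins for temperature and 72 for humidity variables. Bins are half-open
`[e_i, e_{i+1})` with the last bin closed, so no maximum value is lost. A
used range ending exactly on an interior edge does not reach into the
next bin. The used range is the central `trim_level` interval of
occurrence values (linear-interpolation percentiles; level 1 means
min–max), default 0.95, which suppresses the influence of stray extreme
records.

## Ancestral reconstruction

Each bin is a binary presence character; unknown tips enter as the full
state set {0, 1} (parsimony) or partials (1, 1) (likelihood) — the
standard missing-data treatment, so unavailable conditions never create
evidence of change.

**Parsimony.** Minimum-change reconstruction via unit-cost dynamic
programming over the two states (down-pass plus an up-pass over
rest-of-tree costs). This generalization is exact on polytomies and
ambiguous tips, and reports each node's full MPR set — every state
attainable in some most-parsimonious labeling — verified against
exhaustive enumeration over all labelings on trees of up to 6 tips.
Ambiguity ({0, 1}) is reported as *uncertain*, never resolved by an
acctran/deltran convention, because downstream event calls treat
uncertainty explicitly.

**Likelihood.** A symmetric 2-state continuous-time Markov model — the
minimal defensible choice given no prior reason to favor gain over loss —
with stay probability `(1 + e^(-2qt))/2`, uniform (1/2, 1/2) root prior,
and Felsenstein pruning with per-node rescaling. One rate `q` (per MY) is
fitted jointly across all bins of a variable by default: per-bin fitting
of a binary character on a few dozen tips is unstable, and a shared rate
is the natural exchangeability assumption across bins of one gradient
(per-bin fitting remains available). The optimizer is bounded Brent over
**log q** on [1e-8, 10] per MY; a rate is a scale parameter, and on the
linear scale the likelihood surface is so flat near the upper bound that
golden-section steps can stall there, while in log space it is smooth and
unimodal. Hitting the lower bound simply means no change signal and is
flagged, not an error. Marginal posterior state probabilities per node
combine subtree and rest-of-tree partials; they provably sum to 1 and are
verified against brute-force summation over all joint labelings.

**Discretization.** ML probabilities collapse to present at P ≥ 0.95,
absent at P ≤ 0.05, uncertain between — aligned with the 95% confidence
convention used elsewhere in the protocol and configurable. Interior
gaps strictly between present bins are then filled (flagged `filled`) so
each node's niche is contiguous.

## Events, dating, classes, projection

Per branch and bin: absent→present is an expansion, present→absent a
retraction, equal definite states stasis, and any uncertain endpoint
ambiguous — the four labels always sum to the bin count. Events are dated
only to the branch's (parent age, child age) interval; no placement
within a branch is claimed, because nothing in the data constrains it.

Qualitative classes are explicit stand-ins for conventions the
literature leaves undefined: a niche is warm/wet (cold/dry) when its
interval midpoint sits more than 10% of the scheme span above (below)
the scheme midpoint, else intermediate; broad when its present-bin count
strictly exceeds the median across the extant species, else narrow (ties
are narrow). Both thresholds are config keys.

Replicate runs (default 10, seeds `seed..seed+9`) handle trees with
several accessions per species; per-node results are matched across
replicate trees by descendant-species fingerprints and combined by
majority rule (> 50% definite calls win; ties stay uncertain; ML
probabilities are averaged). Majority rule is our documented choice among
reasonable combination rules; unmatched nodes are excluded with a
warning rather than guessed.

Projection marks a cell suitable when its layer value falls in a present
bin (uncertain bins excludable or includable by flag), optionally within
an area mask.

## Synthetic data and what the tests show

The generator emulates the structure of a real study at its default
scale: 24 species, root age 59 MY (Yule topology, with the present
placed one further exponential waiting time after the last split so all
terminal branches are positive), a 66-bin temperature gradient spanning
−5 to 33 (layer units) mapped linearly onto latitude, 30 occurrences per
species drawn uniformly from suitable cells, generous 1000 km accessible
areas, and niche intervals evolving by a compound Poisson process: each
interval side experiences events at 0.02/MY, each moving the boundary by
a Geometric(0.5) number of bins (small shifts dominate — the
conservatism regime), clipped to the scheme and to a minimum width of
one bin. The root interval spans 10 bins (~15% of the gradient), a
moderate extant-like breadth. Every realized event is logged, and
replaying the log reproduces every node's true interval exactly (a
tested invariant).

What the generator does **not** emulate: spatial sampling bias,
georeferencing error, multimodal or disjunct niches, niche–niche
interactions, climate change over the tree's timespan, and correlated
multi-variable evolution. Passing recovery tests therefore demonstrate
the pipeline's internal correctness and its behavior under clean
sampling, not robustness to the biases of real occurrence data.

**Recovery performance.** On 20 default datasets, scored per branch and
bin against the truth log: parsimony-based event calls reach ~0.5
sensitivity at ~0.8 precision; the fitted shared rate lands within a
factor 2 of the realized per-bin flip rate (median ratio ~0.8–0.9); and
tip niches are recovered to well under one bin of midpoint error. The
sensitivity ceiling is a property of the inference problem, not of the
implementation: with tips set to their *true* intervals (no sampling
noise at all) sensitivity rises only to ~0.54, because all lineages'
interval boundaries random-walk over the same few bins, and
minimum-change reconstruction lawfully compresses such parallel and
reversed histories onto fewer branches than truth used. Precision is the
trustworthy direction: events the pipeline does call are mostly real.
Note that the fitted Mk2 rate estimates the per-bin state-flip rate —
about `2 x rate x E[magnitude] / n_bins` per MY — which is an order of
magnitude below the per-side boundary event rate; the two are different
physical quantities and only the former is comparable to `q`.

## Numerical and convention details

- Grids: cell centers carry the values; row 0 is the northernmost row;
  points map to cells by half-open intervals with the extent's maximum
  edges closed. ESRI ASCII round-trips are bit-exact (floats written via
  `repr`).
- Ultrametricity: relative tolerance 1e-6 of root depth, configurable;
  node age = distance to the deepest descendant tip.
- Duplicate-tip pruning merges branch lengths additively through
  suppressed unifurcations, preserving every retained tip's depth.
- PCA layers: variables are z-scored over the fit cells, projected onto
  eigenvectors of the correlation matrix; each component's sign is fixed
  so its largest-magnitude loading is positive. The fit region defaults
  to all jointly valid cells (the analysis extent) rather than
  per-species M, so all species share one component space.
- Determinism: every stochastic step takes an explicit seed; output CSVs
  are sorted and floats formatted at full precision, so identical seeds
  and inputs reproduce byte-identical outputs.
- Degenerate inputs: a single occurrence yields a valid point niche; an
  all-absent reconstruction yields an empty niche with a warning rather
  than an error; a constant layer is rejected by the PCA with a
  zero-variance error.

## Known limitations

- Contiguous-interval smoothing cannot represent disjunct niches.
- Event dating is interval-valued by construction; point dates quoted
  from such analyses are presentation, not inference.
- Per-branch-bin event recall is bounded near ~0.5 under realistic
  conservatism regimes (see above); interpret absence of a detected
  event accordingly.
- The symmetric Mk model assumes equal gain/loss rates and rate
  homogeneity across branches; an asymmetric-rate option exists but
  rate variation across lineages is out of scope.
- GeoTIFF I/O and CRS reprojection are not provided; inputs must be
  geographic-coordinate ASCII grids.
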