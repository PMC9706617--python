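"""Configuration-driven orchestration of the full analysis.

Stages run in order — profiles -> bin tables -> per-replicate ancestral
reconstruction -> consensus -> branch events -> niche classes ->
geographic projections — with every stage's outputs written to the work
directory before the next starts.  Output CSVs are sorted and floats
formatted at full precision, so a rerun with the same seed and inputs
is byte-identical.

Replicates handle trees that carry several accessions per species: each
replicate prunes the tree to one random representative per species
(seeds ``seed .. seed + n_replicates - 1``) and the per-node results are
combined by majority rule across replicates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phyloniche import asr as _asr
from phyloniche import bin_tables as _bt
from phyloniche import niche_evolution as _ev
from phyloniche import niche_profiles as _np
from phyloniche.data_io import (
    EnvLayer,
    LayerStack,
    Phylo,
    read_layer,
    read_newick,
    read_occurrences,
    resolve_duplicate_tips,
    write_layer,
)

__all__ = ["PipelineConfig", "run", "load_profiles"]

logger = logging.getLogger("phyloniche")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults follow the standard protocol.

    Shipped defaults: 66 bins for temperature variables and 72 for
    humidity variables, 500 km accessible-area buffers, a 95% trim
    level on used ranges, a 0.95 ML discretization threshold and 10
    replicate tip resolutions.
    """

    occurrences: str = ""
    tree: str = ""
    layers: dict[str, str] = field(default_factory=dict)
    workdir: str = "run"
    n_bins: dict[str, int] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    buffer_km: float = _np.DEFAULT_BUFFER_KM
    trim_level: float = _np.DEFAULT_TRIM_LEVEL
    unknown_policy: str = "peripheral"
    asr_methods: list[str] = field(default_factory=lambda: ["parsimony", "likelihood"])
    event_method: str = "parsimony"
    ml_threshold: float = _asr.DEFAULT_ML_THRESHOLD
    n_replicates: int = 10
    pad: float = _bt.DEFAULT_PAD
    seed: int = 0
    species_map: dict[str, str] | None = None
    occurrence_columns: list[str] = field(
        default_factory=lambda: ["species", "longitude", "latitude"]
    )

    def kind_of(self, variable_id: str) -> str:
        if variable_id in self.kinds:
            return self.kinds[variable_id]
        return "humidity" if "hum" in variable_id.lower() else "temperature"

    def n_bins_for(self, variable_id: str) -> int:
        if variable_id in self.n_bins:
            return self.n_bins[variable_id]
        return _bt.DEFAULT_N_BINS[self.kind_of(variable_id)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _fmt(x: float) -> str:
    return repr(float(x))


def load_profiles(path: str | Path) -> list[_np.NicheProfile]:
    """Read a profiles.csv written by the profile stage."""
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            _np.NicheProfile(
                species=str(r["species"]),
                variable_id=str(r["variable"]),
                used_range=(float(r["used_lo"]), float(r["used_hi"])),
                available_range=(float(r["avail_lo"]), float(r["avail_hi"])),
                n_occurrences=int(r["n_occ"]),
                trim_level=float(r["trim_level"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_profiles(
    config: PipelineConfig,
    stack: LayerStack,
    by_species: dict[str, list],
    workdir: Path,
) -> tuple[dict[str, list[_np.NicheProfile]], dict[str, _np.AccessibleArea]]:
    """Accessible areas and niche profiles for every species x variable."""
    ref = stack[0]
    joint_valid = stack.valid_mask
    geometry = EnvLayer(
        values=np.where(joint_valid, ref.values, 0.0),
        nodata_mask=~joint_valid,
        extent=ref.extent,
        resolution=ref.resolution,
        variable_id="geometry",
    )
    profiles: dict[str, list[_np.NicheProfile]] = {lyr.variable_id: [] for lyr in stack}
    areas: dict[str, _np.AccessibleArea] = {}
    for sp in sorted(by_species):
        recs = by_species[sp]
        area = _np.build_accessible_area(recs, geometry, buffer_km=config.buffer_km)
        areas[sp] = area
        for lyr in stack:
            use, _skipped = _np.extract_use(recs, lyr)
            avail = _np.extract_availability(area, lyr)
            profiles[lyr.variable_id].append(
                _np.make_profile(sp, lyr.variable_id, use, avail, config.trim_level)
            )
    rows = []
    for var in sorted(profiles):
        for p in sorted(profiles[var], key=lambda p: p.species):
            rows.append(
                [p.species, var, _fmt(p.used_range[0]), _fmt(p.used_range[1]),
                 _fmt(p.available_range[0]), _fmt(p.available_range[1]),
                 p.n_occurrences, _fmt(p.trim_level)]
            )
    pd.DataFrame(
        rows,
        columns=["species", "variable", "used_lo", "used_hi", "avail_lo",
                 "avail_hi", "n_occ", "trim_level"],
    ).to_csv(workdir / "profiles.csv", index=False)
    for sp, area in sorted(areas.items()):
        m_layer = EnvLayer(
            values=area.mask.astype(float),
            nodata_mask=np.zeros(area.mask.shape, dtype=bool),
            extent=ref.extent,
            resolution=ref.resolution,
            variable_id=f"M_{sp}",
        )
        write_layer(m_layer, workdir / "areas" / f"M_{sp}.asc")
    return profiles, areas


def stage_bins(
    config: PipelineConfig,
    profiles: dict[str, list[_np.NicheProfile]],
    workdir: Path,
) -> dict[str, _bt.BinTable]:
    """Global bin scheme and ternary character table per variable."""
    tables: dict[str, _bt.BinTable] = {}
    for var in sorted(profiles):
        scheme = _bt.build_bin_scheme(profiles[var], config.n_bins_for(var), pad=config.pad)
        table = _bt.BinTable(scheme=scheme)
        for p in profiles[var]:
            table.add(p.species, _bt.assign_states(p, scheme, config.unknown_policy))
        _bt.write_bin_table(table, workdir / f"bin_table_{var}.csv")
        tables[var] = table
    return tables


def _final_states(
    rec: _asr.NodeReconstruction, method: str, ml_threshold: float
) -> _asr.NicheVector:
    states = _asr.states_from_reconstruction(rec, method=method, ml_threshold=ml_threshold)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return _asr.smooth_niche(states)


def stage_asr(
    config: PipelineConfig,
    phylo: Phylo,
    tables: dict[str, _bt.BinTable],
    workdir: Path,
) -> tuple[dict[str, dict[frozenset, _asr.NodeReconstruction]], Phylo]:
    """Per-replicate reconstruction and majority consensus per variable.

    Returns consensus reconstructions keyed by descendant-species
    fingerprint, plus the reference (first-replicate) tree.
    """
    methods = tuple(config.asr_methods)
    consensus: dict[str, dict[frozenset, _asr.NodeReconstruction]] = {}
    ref_tree: Phylo | None = None
    for var in sorted(tables):
        table = tables[var]
        replicate_maps = []
        for rep in range(config.n_replicates):
            tree_r = resolve_duplicate_tips(
                phylo, config.seed + rep, species_map=config.species_map
            )
            if ref_tree is None:
                ref_tree = tree_r
            recs, fit = _asr.reconstruct_table(
                tree_r, table, methods=methods, ml_threshold=config.ml_threshold
            )
            fingerprints = tree_r.tip_descendant_sets()
            replicate_maps.append({fingerprints[nid]: r for nid, r in recs.items()})
            _write_reconstruction(
                workdir / f"reconstruction_{var}_rep{rep}.csv",
                tree_r, recs, var, rep, methods, config.ml_threshold,
            )
            if fit is not None and not isinstance(fit, list):
                logger.info("%s rep %d fitted rate q=%.6g", var, rep, fit.q)
        consensus[var] = _ev.combine_replicates(replicate_maps)
        _write_consensus(
            workdir / f"consensus_{var}.csv",
            ref_tree, consensus[var], var, methods, config.ml_threshold,
        )
    (workdir / "reference_tree.nwk").write_text(_annotated_newick(ref_tree) + "\n")
    return consensus, ref_tree


def _annotated_newick(phylo: Phylo) -> str:
    tree = phylo.tree.clone(depth=1)
    for node, orig in zip(tree.postorder_node_iter(), phylo.postorder()):
        if not node.is_leaf():
            node.label = f"n{orig.node_id}"
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def _parsimony_glyph(s: frozenset) -> str:
    return _bt.PRESENT if s == {1} else _bt.ABSENT if s == {0} else _bt.UNKNOWN


def _write_reconstruction(path, phylo, recs, var, rep, methods, ml_threshold) -> None:
    rows = []
    for node in phylo.postorder():
        rec = recs[node.node_id]
        niche = _final_states(
            rec,
            "parsimony" if "parsimony" in methods else "likelihood",
            ml_threshold,
        )
        for b in range(niche.states.size):
            rows.append([
                rep,
                node.node_id,
                var,
                b,
                _parsimony_glyph(rec.parsimony_sets[b]) if rec.parsimony_sets else "",
                _fmt(rec.ml_prob_present[b]) if rec.ml_prob_present is not None else "",
                niche.states[b],
                int(niche.filled[b]),
            ])
    pd.DataFrame(
        rows,
        columns=["tree_id", "node_id", "variable", "bin_index",
                 "parsimony_state", "ml_prob", "final_state", "filled_flag"],
    ).to_csv(path, index=False)


def _write_consensus(path, ref_tree, cons, var, methods, ml_threshold) -> None:
    fingerprints = ref_tree.tip_descendant_sets()
    rows = []
    for node in ref_tree.postorder():
        key = fingerprints[node.node_id]
        if key not in cons:
            continue
        rec = cons[key]
        niche = _final_states(
            rec,
            "parsimony" if "parsimony" in methods else "likelihood",
            ml_threshold,
        )
        for b in range(niche.states.size):
            rows.append([
                node.node_id,
                var,
                b,
                _parsimony_glyph(rec.parsimony_sets[b]) if rec.parsimony_sets else "",
                _fmt(rec.ml_prob_present[b]) if rec.ml_prob_present is not None else "",
                niche.states[b],
                int(niche.filled[b]),
            ])
    pd.DataFrame(
        rows,
        columns=["node_id", "variable", "bin_index", "parsimony_state",
                 "ml_prob", "final_state", "filled_flag"],
    ).to_csv(path, index=False)


def _consensus_niches(
    config: PipelineConfig,
    ref_tree: Phylo,
    cons: dict[frozenset, _asr.NodeReconstruction],
    method: str,
) -> dict[int, _asr.NicheVector]:
    fingerprints = ref_tree.tip_descendant_sets()
    out = {}
    for node in ref_tree.postorder():
        key = fingerprints[node.node_id]
        if key in cons:
            out[node.node_id] = _final_states(cons[key], method, config.ml_threshold)
    return out


def stage_events(
    config: PipelineConfig,
    ref_tree: Phylo,
    niches: dict[int, _asr.NicheVector],
    var: str,
    workdir: Path,
) -> list[_ev.EventSummary]:
    """Branch-by-branch change detection and dating on the reference tree."""
    changes: list[_ev.BranchChange] = []
    for node in ref_tree.preorder():
        for child in node.child_nodes():
            if node.node_id in niches and child.node_id in niches:
                changes.extend(
                    _ev.compare_branch(
                        niches[node.node_id], niches[child.node_id],
                        parent_id=node.node_id, child_id=child.node_id,
                    )
                )
    summaries = _ev.summarize_events(ref_tree, changes)
    pd.DataFrame(
        [[s.parent, s.child, _fmt(s.parent_age), _fmt(s.child_age),
          s.n_expansion, s.n_retraction, s.n_ambiguous] for s in summaries],
        columns=["parent", "child", "parent_age", "child_age",
                 "n_expansion", "n_retraction", "n_ambiguous"],
    ).to_csv(workdir / f"events_{var}.csv", index=False)
    return summaries


def stage_classes(
    config: PipelineConfig,
    ref_tree: Phylo,
    niches: dict[int, _asr.NicheVector],
    scheme: _bt.BinScheme,
    var: str,
    workdir: Path,
) -> dict[int, _ev.NicheClass]:
    """Qualitative warm/cold (wet/dry) and broad/narrow labels per node."""
    tip_ids = {n.node_id for n in ref_tree.postorder() if n.is_leaf()}
    reference = [nv for nid, nv in niches.items() if nid in tip_ids and nv.interval]
    classes = {}
    for nid in sorted(niches):
        nv = niches[nid]
        if nv.interval is None:
            continue
        classes[nid] = _ev.classify_niche(
            nv, scheme, reference, kind=config.kind_of(var), node_id=nid
        )
    pd.DataFrame(
        [[nid, c.position, c.breadth] for nid, c in sorted(classes.items())],
        columns=["node", "position", "breadth"],
    ).to_csv(workdir / f"classes_{var}.csv", index=False)
    return classes


def stage_projections(
    config: PipelineConfig,
    ref_tree: Phylo,
    niches: dict[int, _asr.NicheVector],
    scheme: _bt.BinScheme,
    layer: EnvLayer,
    workdir: Path,
) -> None:
    """0/1 rasters of each internal node's reconstructed niche."""
    proj_dir = workdir / "projections"
    proj_dir.mkdir(exist_ok=True)
    for node in ref_tree.postorder():
        if node.is_leaf() or node.node_id not in niches:
            continue
        nv = niches[node.node_id]
        if nv.interval is None:
            continue
        mask = _ev.project_niche(nv, layer, scheme)
        out = EnvLayer(
            values=mask.astype(float),
            nodata_mask=layer.nodata_mask.copy(),
            extent=layer.extent,
            resolution=layer.resolution,
            variable_id=f"{scheme.variable_id}_n{node.node_id}",
        )
        write_layer(out, proj_dir / f"{scheme.variable_id}_node{node.node_id}.asc")


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the work directory.

    Stage order: profiles -> bins -> ASR (replicates + consensus) ->
    events -> classes -> projections.  A failure aborts with the stage
    name in the exception; outputs written so far are left in place.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    (workdir / "areas").mkdir(exist_ok=True)

    for label, p in (("occurrences", config.occurrences), ("tree", config.tree),
                     *[(f"layer {v}", p) for v, p in config.layers.items()]):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")

    log_path = workdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    config.to_yaml(workdir / "config.yaml")

    stage = "inputs"
    try:
        t0 = time.perf_counter()
        records, report = read_occurrences(
            config.occurrences, dedupe=False,
            columns=tuple(config.occurrence_columns),
        )
        by_species: dict[str, list] = {}
        for r in records:
            by_species.setdefault(r.species, []).append(r)
        stack = LayerStack(
            [read_layer(p, variable_id=v) for v, p in sorted(config.layers.items())]
        )
        phylo = read_newick(config.tree)
        logger.info(
            "inputs: %d records (%d dropped), %d species, %d layers, %d tips; seed %d",
            len(records), report.n_dropped, len(by_species), len(stack),
            phylo.n_tips, config.seed,
        )

        stage = "profiles"
        profiles, areas = stage_profiles(config, stack, by_species, workdir)
        logger.info("profiles done in %.2fs", time.perf_counter() - t0)

        stage = "bins"
        tables = stage_bins(config, profiles, workdir)

        stage = "asr"
        consensus, ref_tree = stage_asr(config, phylo, tables, workdir)

        for var in sorted(tables):
            niches = _consensus_niches(
                config, ref_tree, consensus[var], config.event_method
            )
            stage = f"events[{var}]"
            stage_events(config, ref_tree, niches, var, workdir)
            stage = f"classes[{var}]"
            stage_classes(config, ref_tree, niches, tables[var].scheme, var, workdir)
            stage = f"projections[{var}]"
            stage_projections(
                config, ref_tree, niches, tables[var].scheme, stack[var], workdir
            )
        logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return workdir
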