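"""End-to-end design pipeline: mesh -> routing -> cylinders -> nucleotides ->
sequences -> export, with validators at every stage.

The workflow is the same for every method; only the routing step and the
sequence generator differ.  ``run_design`` writes the routing report, the
oxDNA pair, a UNF document and the strand CSV into the output directory and
returns a machine-readable report with the validator results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import routing as rt
from .cylinders import (
    CylinderModel,
    DesignParameters,
    HelixGeometry,
    build_cylinder_model,
    relax,
    spring_objective,
)
from .errors import ParameterError, RoutingError, StageError, WireweaverError
from .graph import (
    Route,
    WireframeGraph,
    check_double_coverage,
    check_single_coverage,
    check_walks_closed,
    route_to_text,
)
from .io_export import unf_to_json, write_csv, write_oxdna, write_unf
from .mesh import Mesh, analyze_topology, parse_obj
from .nucleotides import (
    NucleotideModel,
    add_linkers,
    instantiate_nucleotides,
    nick_strands,
    reroute_kissing_loops,
)
from .sequences import (
    SequenceConstraints,
    assign_kissing_loops,
    assign_random,
    assign_scaffold,
    export_nupack,
    fms_optimize,
    load_kissing_loop_table,
    random_sequence,
    read_fasta,
    wc_complement,
)

__all__ = ["RunConfig", "run_design", "route_only", "design_from_mesh"]

METHODS = ("at-dna", "st-dna", "cc-dna", "st-rna", "xt-rna")
RNA_METHODS = ("st-rna", "xt-rna")


@dataclass
class RunConfig:
    """Reproducible configuration of a design run."""

    input_path: str = ""
    method: str = "st-dna"
    scale: float = 10.0
    min_overlap: int = 8
    seed: int = 0
    relax: bool = False
    relax_iterations: int = 100
    sequence_mode: str = "auto"  # auto | random | scaffold | fms | none
    scaffold_path: str | None = None
    fms_iterations: int = 500
    gc_bounds: tuple[float, float] = (0.0, 1.0)
    forbidden: tuple[str, ...] = ()
    output_dir: str = "."
    verbosity: int = 1
    atrail_time_limit: float | None = 60.0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}; choose {METHODS}")
        if self.sequence_mode == "scaffold" and self.method not in ("at-dna", "st-dna"):
            raise ParameterError("a scaffold file only applies to at-dna / st-dna")
        if self.sequence_mode == "fms" and self.method != "cc-dna":
            raise ParameterError("fms sequence design only applies to cc-dna")
        if self.scaffold_path and self.method == "cc-dna":
            raise ParameterError("cc-dna is scaffold-free; scaffold file is illegal")
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except WireweaverError as exc:
                if isinstance(exc, StageError):
                    raise
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("routing")
def route_mesh(mesh: Mesh, method: str, atrail_time_limit: float | None = 60.0):
    """Route a mesh with the requested method; returns (graph, route)."""
    graph = WireframeGraph.from_mesh(mesh)
    report = analyze_topology(mesh)
    if method == "at-dna":
        if not (report.is_closed_manifold and report.is_orientable):
            raise RoutingError(
                "the A-trail method needs a closed orientable 2-manifold mesh; "
                "this mesh has boundary or inconsistent face orientations -- "
                "repair the mesh or use st-dna / cc-dna"
            )
        recond = rt.recondition(graph)
        result = rt.atrail_search(recond, time_limit=atrail_time_limit)
        if not result.found:
            state = "proved absent" if result.exhausted else "not found in time"
            raise RoutingError(f"A-trail {state} ({result.nodes} nodes explored)")
        route = result.route
        if report.genus and report.genus > 0:
            route.annotations.setdefault("warnings", []).append(
                "toroidal mesh: A-trail found but unknottedness is not guaranteed"
            )
        return recond, route
    if method == "st-dna":
        tree = rt.prim_max_branching_tree(graph, seed_vertex=min(graph.positions))
        return graph, rt.st_route(graph, tree)
    if method == "cc-dna":
        return graph, rt.cycle_cover(graph, faces=mesh.faces)
    if method == "st-rna":
        tree = rt.prim_max_branching_tree(graph, seed_vertex=min(graph.positions))
        return graph, rt.st_rna_route(graph, tree)
    if method == "xt-rna":
        tree = rt.xuong_tree(graph, mode="auto")
        return graph, rt.xt_route(graph, tree)
    raise ParameterError(f"unknown method {method!r}")


def validate_route(route: Route, graph: WireframeGraph) -> dict:
    check_walks_closed(route)
    validators: dict = {"walks": len(route.walks), "traversals": route.n_traversals}
    if route.method == "at-dna":
        check_single_coverage(route, graph)
        problems = rt.check_sharp_turns(graph, route)
        validators["coverage"] = "each reconditioned edge once"
        validators["sharp_turn_violations"] = len(problems)
    else:
        check_double_coverage(route, graph)
        validators["coverage"] = "each edge twice, antiparallel"
        if route.method == "cc-dna":
            rt.check_junction_connectivity(route, graph)
            validators["junctions_connected"] = True
    validators["kissing_loops"] = len(
        {t.edge_id for t in route.all_traversals() if t.kissing_loop}
    )
    return validators


@_stage("cylinders")
def _build_cylinders(route, graph, params, geom, do_relax, relax_iterations, seed):
    model = build_cylinder_model(route, graph, params, geom)
    report = {
        "cylinders": len(model.cylinders),
        "links": len(model.links),
        "diameter_nm": geom.diameter,
        "spring_objective": spring_objective(model),
    }
    if do_relax:
        model = relax(model, iterations=relax_iterations, seed=seed)
        report["spring_objective_relaxed"] = spring_objective(model)
    return model, report


@_stage("nucleotides")
def _build_nucleotides(cyl_model: CylinderModel, route: Route, params: DesignParameters):
    model = instantiate_nucleotides(cyl_model)
    if cyl_model.method in RNA_METHODS:
        reroute_kissing_loops(model, cyl_model, kl_loop_len=params.kl_loop_len)
    add_linkers(model, cyl_model, params)
    model.nick_edge = route.annotations.get("nick_edge")
    nick_strands(model, params.min_overlap)
    model.check_pairing()
    return model


@_stage("sequences")
def _assign_sequences(model: NucleotideModel, config: RunConfig, route: Route):
    mode = config.sequence_mode
    report: dict = {}
    if mode == "auto":
        mode = {"at-dna": "random", "st-dna": "random", "cc-dna": "fms"}.get(
            config.method, "random"
        )
        if config.scaffold_path and config.method in ("at-dna", "st-dna"):
            mode = "scaffold"
    if mode == "none":
        return report
    if mode in ("scaffold", "random") and config.method in ("at-dna", "st-dna"):
        if mode == "scaffold":
            seq = read_fasta(config.scaffold_path)
        else:
            need = sum(
                1 for nt in model.nucleotides if nt.role == "scaffold"
            )
            seq = random_sequence(need, seed=config.seed)
        assign_scaffold(model, seq)
        report["sequence_mode"] = mode
    elif mode == "fms":
        constraints = SequenceConstraints(
            gc_bounds=config.gc_bounds, forbidden=config.forbidden, alphabet="DNA"
        )
        fms = fms_optimize(
            model, constraints, seed=config.seed, max_iters=config.fms_iterations
        )
        report["sequence_mode"] = "fms"
        report["longest_repeated_substring"] = fms.final_objective
    else:  # random assignment (RNA and fallback)
        assign_random(model, seed=config.seed)
        report["sequence_mode"] = "random"
    if config.method in RNA_METHODS and model.kl_groups:
        table = load_kissing_loop_table()
        assign_kissing_loops(model, table)
        report["kissing_loop_pairs"] = len(model.kl_groups)
    return report


def _complementarity_ok(model: NucleotideModel) -> bool:
    alphabet = model.geom.nucleic_acid if model.geom else "DNA"
    for nt in model.nucleotides:
        if nt.pair != -1 and nt.base != "N":
            other = model.nuc(nt.pair)
            if other.base != "N" and other.base != wc_complement(nt.base, alphabet):
                return False
    return True


def _staple_histogram(model: NucleotideModel) -> dict[int, int]:
    hist: dict[int, int] = {}
    for s in model.strands():
        if s.role in ("staple", "strand"):
            hist[len(s.ids)] = hist.get(len(s.ids), 0) + 1
    return dict(sorted(hist.items()))


def design_from_mesh(mesh: Mesh, config: RunConfig):
    """Run the full pipeline on an in-memory mesh.

    Returns ``(report, artifacts)`` where artifacts holds the route, the
    cylinder model, the nucleotide model and the export documents.
    """
    config.validate()
    geom = HelixGeometry.rna() if config.method in RNA_METHODS else HelixGeometry.dna()
    params = DesignParameters(
        method=config.method,
        scale=config.scale,
        min_overlap=config.min_overlap,
        gc_bounds=config.gc_bounds,
        forbidden=config.forbidden,
        seed=config.seed,
    )
    graph, route = route_mesh(mesh, config.method, config.atrail_time_limit)
    route_validators = validate_route(route, graph)
    cyl_model, cyl_report = _build_cylinders(
        route, graph, params, geom,
        config.relax, config.relax_iterations, config.seed,
    )
    nuc_model = _build_nucleotides(cyl_model, route, params)
    seq_report = _assign_sequences(nuc_model, config, route)
    strands = nuc_model.strands()
    validators = {
        "route": route_validators,
        "complementarity": _complementarity_ok(nuc_model),
        "staple_length_histogram": _staple_histogram(nuc_model),
        "warnings": list(nuc_model.warnings)
        + list(route.annotations.get("warnings", [])),
    }
    report = {
        "method": config.method,
        "seed": config.seed,
        "scale_nm": config.scale,
        "n_nucleotides": nuc_model.n_nucleotides,
        "n_strands": len(strands),
        "cylinders": cyl_report,
        "sequences": seq_report,
        "validators": validators,
        "ok": bool(validators["complementarity"]),
    }
    artifacts = {
        "graph": graph,
        "route": route,
        "cylinder_model": cyl_model,
        "nucleotide_model": nuc_model,
    }
    return report, artifacts


def run_design(config: RunConfig) -> dict:
    """Full pipeline from an OBJ file on disk; writes all export files."""
    with open(config.input_path) as fh:
        mesh = parse_obj(fh.read())
    report, artifacts = design_from_mesh(mesh, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = artifacts["nucleotide_model"]
    allow_n = config.sequence_mode == "none"
    pair = write_oxdna(model)
    (outdir / "design.top").write_text(pair.topology)
    (outdir / "design.dat").write_text(pair.configuration)
    (outdir / "design.unf.json").write_text(unf_to_json(write_unf(model)))
    (outdir / "strands.csv").write_text(write_csv(model, allow_n=allow_n))
    (outdir / "route.txt").write_text(route_to_text(artifacts["route"]))
    if config.method in RNA_METHODS:
        (outdir / "design.npk").write_text(export_nupack(model))
    cfg = asdict(config)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def route_only(config: RunConfig) -> dict:
    """Routing stage alone: returns the validator report, writes route.txt."""
    with open(config.input_path) as fh:
        mesh = parse_obj(fh.read())
    config.validate()
    graph, route = route_mesh(mesh, config.method, config.atrail_time_limit)
    validators = validate_route(route, graph)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "route.txt").write_text(route_to_text(route))
    report = {"method": config.method, "validators": validators}
    (outdir / "route_report.json").write_text(json.dumps(report, indent=1))
    return report
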