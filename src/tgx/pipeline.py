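"""End-to-end analytical flow: score -> radar charts -> heat map -> network.

A run is fully described by a :class:`RunConfig`; given the same config and
input files it reproduces byte-identical outputs and manifest hashes.  The
manifest records tool version, config hash, input/output checksums and
per-stage status, so a run can be audited without re-executing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from . import io as tgx_io
from . import network as net
from . import scoring, viz
from .errors import TgxError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    expression: str
    sets: str
    design: str
    out_dir: str
    calls: str | None = None
    phenotypes: str | None = None
    supervised_spec: str | None = None
    supervised_condition: str | None = None
    method: str = "dscore"
    scale: float = 10.0
    min_abs_effect: float = 0.0
    linear: bool = False
    reference_level: float = 20.0
    heatmap_ordering: str = "input"
    shrinkage: str | float = "auto"
    edge_rule: str = "abs:0.1"
    n_permutations: int = 200
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        verbosity excluded, so relocated reruns hash identically)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def parse_edge_rule(rule: str) -> dict:
    """Parse 'abs:t', 'top:k' or 'fdr:q' into select_edges keyword arguments."""
    try:
        kind, _, value = rule.partition(":")
        if kind == "abs":
            return {"rule": "abs_threshold", "threshold": float(value)}
        if kind == "top":
            return {"rule": "top_k", "k": int(value)}
        if kind == "fdr":
            return {"rule": "perm_fdr", "q": float(value)}
    except ValueError as exc:
        raise ValidationError(f"cannot parse edge rule {rule!r}: {exc}") from exc
    raise ValidationError(f"unknown edge rule {rule!r}; expected abs:t, top:k or fdr:q")


@dataclass
class _Manifest:
    config: RunConfig
    stages: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        doc = {
            "tool": "tgx",
            "version": __version__,
            "config_hash": self.config.hash(),
            "config": self.config.to_dict(),
            "inputs": self.inputs,
            "stages": self.stages,
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")


def run_flow(config: RunConfig) -> Path:
    """Execute the full flow; returns the output directory.

    Stage order: load inputs, score, radar chart per condition, heat map,
    partial-correlation network (plus exports), optional supervised network.
    A failing stage aborts the run with the stage name; outputs already
    produced stay on disk and are flagged in the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config=config)
    provenance = [f"tgx {__version__}", f"config {config.hash()}"]

    def record_output(path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    def fail(stage: str, exc: Exception) -> TgxError:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.write(out_dir / "manifest.json")
        return TgxError(f"stage {stage!r} failed: {exc}")

    # -- load ---------------------------------------------------------------
    stage = "load"
    try:
        for key in ("expression", "calls", "sets", "design", "phenotypes",
                    "supervised_spec"):
            path = getattr(config, key)
            if path is not None:
                manifest.inputs[key] = _sha256(Path(path))
        bundle = tgx_io.read_expression(config.expression, config.calls)
        if config.linear:
            bundle = tgx_io.ExpressionBundle(
                values=tgx_io.log2_transform(bundle.values), calls=bundle.calls)
        sets = tgx_io.read_gmt(config.sets)
        design = tgx_io.read_design(config.design)
        phenos = (tgx_io.read_phenotypes(config.phenotypes)
                  if config.phenotypes else None)
        manifest.stages[stage] = "ok"
    except Exception as exc:
        raise fail(stage, exc) from exc

    # -- score --------------------------------------------------------------
    stage = "score"
    try:
        table = scoring.score_all(bundle, design, sets, method=config.method,
                                  scale=config.scale,
                                  min_abs_effect=config.min_abs_effect)
        score_path = out_dir / "scores.tsv"
        tgx_io.write_scores(table, score_path, comments=provenance)
        record_output(score_path)
        manifest.stages[stage] = "ok"
    except Exception as exc:
        raise fail(stage, exc) from exc

    # -- radar charts -------------------------------------------------------
    stage = "radar"
    try:
        for cond in table.scores.columns:
            path = out_dir / f"radar_{cond}.svg"
            viz.radar_chart(table, cond, path, reference_level=config.reference_level)
            record_output(path)
        manifest.stages[stage] = "ok"
    except Exception as exc:
        raise fail(stage, exc) from exc

    # -- heat map -----------------------------------------------------------
    stage = "heatmap"
    try:
        path = out_dir / "heatmap.svg"
        viz.heat_map(table, path, ordering=config.heatmap_ordering)
        record_output(path)
        manifest.stages[stage] = "ok"
    except Exception as exc:
        raise fail(stage, exc) from exc

    # -- network ------------------------------------------------------------
    stage = "network"
    try:
        features = net.assemble_features(table, phenos)
        shrink = config.shrinkage
        if isinstance(shrink, str) and shrink != "auto":
            shrink = float(shrink)
        graph = net.estimate_pcor(features, shrinkage=shrink)
        kwargs = parse_edge_rule(config.edge_rule)
        if kwargs["rule"] == "perm_fdr":
            kwargs.update(features=features, n_permutations=config.n_permutations,
                          seed=config.seed)
        edges = net.select_edges(graph, **kwargs)
        for fmt, suffix in (("graphml", "network.graphml"), ("dot", "network.dot"),
                            ("tsv", "network.edges.tsv")):
            path = out_dir / suffix
            net.export_network(graph, edges, path, fmt=fmt, comments=provenance)
            record_output(path)
        manifest.stages[stage] = f"ok (lambda={graph.shrinkage:.6f}, {len(edges)} edges)"
    except Exception as exc:
        raise fail(stage, exc) from exc

    # -- supervised network -------------------------------------------------
    stage = "supervised"
    if config.supervised_spec:
        try:
            spec = viz.SupervisedNetworkSpec.from_tsv(config.supervised_spec)
            cond = config.supervised_condition or table.scores.columns[-1]
            dot = viz.render_supervised_network(spec, table, cond,
                                                out_dir / "supervised",
                                                comments=provenance)
            record_output(dot)
            manifest.stages[stage] = "ok"
        except Exception as exc:
            raise fail(stage, exc) from exc
    else:
        manifest.stages[stage] = "skipped (no supervised spec)"

    manifest.write(out_dir / "manifest.json")
    return out_dir
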