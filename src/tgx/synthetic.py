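"""Synthetic data with planted ground truth, at two levels.

*Expression level*: probe x sample log2 matrices with biomarker gene sets
perturbed by known log2 effects, plus intensity-linked detection calls —
low-intensity probes are called Marginal/Absent more often, so quality
weighting has real signal to exploit.

*Feature level*: condition x feature draws from a multivariate normal whose
precision matrix (hence partial-correlation graph) is known exactly, for
testing network-edge recovery.

A bromobenzene-like case study combines the two ideas into a four-timepoint
hepatotoxicity time course with a planted effect schedule: glutathione
depletion and DNA damage first, then oxidative stress and inflammation,
peak inflammation and suppressed energy metabolism at the last timepoint.

Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from . import io as tgx_io
from .io import (DesignTable, ExpressionBundle, GeneSetCollection,
                 PhenotypeTable, ScoreTable)


@dataclass
class ConditionSpec:
    """One treatment condition and its planted per-set log2 effects."""

    condition_id: str
    deltas: dict[str, float] = field(default_factory=dict)
    compound: str = "compound_A"
    dose: str = "high"
    timepoint_h: float = 24.0


@dataclass
class SimulationConfig:
    """Parameters of the expression-level generator.

    Defaults emulate a liver-microarray biomarker screen: 58 gene sets of
    8–15 probes on a 1,200-probe array, 3 replicates per group, log2
    baselines around 8 +/- 2 with replicate noise SD 0.3, and a logistic
    detection-call model centered at log2 intensity 6.
    """

    n_probes: int = 1200
    n_sets: int = 58
    set_size: tuple[int, int] = (8, 15)
    replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    call_center: float = 6.0
    call_scale: float = 1.0
    marginal_band: float = 1.0
    overlap: bool = False
    set_names: list[str] | None = None
    conditions: list[ConditionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_sets <= 0 or self.replicates <= 0:
            raise ConfigError("n_probes, n_sets and replicates must be positive")
        lo, hi = self.set_size
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid set_size range {self.set_size}")
        if self.baseline_sd < 0 or self.noise_sd < 0 or self.call_scale <= 0:
            raise ConfigError("scale parameters must be non-negative (call_scale positive)")
        if not self.overlap and self.n_sets * hi > self.n_probes:
            raise ConfigError(
                f"disjoint sets need n_probes >= n_sets*max_size = {self.n_sets * hi}"
            )
        if self.set_names is not None and len(self.set_names) != self.n_sets:
            raise ConfigError("set_names length must equal n_sets")
        if not self.conditions:
            self.conditions = [ConditionSpec(condition_id="cond_1", deltas={})]
        names = self.set_names or _default_set_names(self.n_sets)
        for cond in self.conditions:
            unknown = set(cond.deltas) - set(names)
            if unknown:
                raise ConfigError(
                    f"condition {cond.condition_id!r} perturbs unknown set(s): {sorted(unknown)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = [ConditionSpec(**c) for c in d["conditions"]]
        if "set_size" in d:
            d["set_size"] = tuple(d["set_size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """What the generator planted, for assertable recovery tests."""

    perturbations: dict[str, dict[str, float]] = field(default_factory=dict)
    precision: np.ndarray | None = None
    feature_names: list[str] | None = None
    edges: list[tuple[str, str]] | None = None

    def to_yaml(self, path: str | Path) -> None:
        doc: dict = {"perturbations": {c: dict(d) for c, d in self.perturbations.items()}}
        if self.edges is not None:
            doc["edges"] = [list(e) for e in self.edges]
        if self.feature_names is not None:
            doc["feature_names"] = list(self.feature_names)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _default_set_names(n_sets: int) -> list[str]:
    return [f"set_{i + 1:02d}" for i in range(n_sets)]


# ---------------------------------------------------------------------------
# Expression-level generator
# ---------------------------------------------------------------------------

def _detection_calls(values: np.ndarray, rng: np.random.Generator,
                     center: float, scale: float, band: float) -> np.ndarray:
    """Intensity-linked call model: P w.p. logistic((v-c)/s), else M near the
    detection boundary, else A."""
    p_present = 1.0 / (1.0 + np.exp(-(values - center) / scale))
    u = rng.uniform(size=values.shape)
    calls = np.where(u < p_present, "P",
                     np.where(np.abs(values - center) <= band, "M", "A"))
    return calls


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionBundle, DesignTable,
                                   GeneSetCollection, GroundTruth]:
    """Generate a probe x sample bundle with planted gene-set effects.

    Sample value = probe baseline + planted treated effect + N(0, noise_sd);
    baselines ~ N(baseline_mean, baseline_sd).  Gene sets are disjoint by
    default (crisp recovery tests) or sampled with replacement across sets
    when ``overlap`` is on.
    """
    rng = np.random.default_rng(config.seed)
    probe_ids = [f"probe_{i + 1:05d}" for i in range(config.n_probes)]
    set_names = config.set_names or _default_set_names(config.n_sets)

    lo, hi = config.set_size
    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    sets: dict[str, list[str]] = {}
    if config.overlap:
        for name, size in zip(set_names, sizes):
            sets[name] = [probe_ids[j] for j in sorted(rng.choice(
                config.n_probes, size=size, replace=False))]
    else:
        pool = rng.permutation(config.n_probes)
        cursor = 0
        for name, size in zip(set_names, sizes):
            sets[name] = [probe_ids[j] for j in sorted(pool[cursor:cursor + size])]
            cursor += size
    collection = GeneSetCollection(
        sets=sets, descriptions={n: "synthetic biomarker set" for n in set_names})

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_probes)

    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    design_rows: list[dict] = []
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    for cond in config.conditions:
        shift = np.zeros(config.n_probes)
        for set_name, delta in cond.deltas.items():
            for probe in sets[set_name]:
                shift[probe_pos[probe]] += delta
        for role, role_shift in (("control", 0.0), ("treated", 1.0)):
            for rep in range(config.replicates):
                sid = f"{cond.condition_id}_{role}_{rep + 1}"
                noise = rng.normal(0.0, config.noise_sd, size=config.n_probes)
                columns.append(baseline + role_shift * shift + noise)
                sample_ids.append(sid)
                design_rows.append({
                    "sample_id": sid, "condition_id": cond.condition_id,
                    "role": role, "compound": cond.compound, "dose": cond.dose,
                    "timepoint_h": cond.timepoint_h,
                })

    values = pd.DataFrame(np.column_stack(columns), index=probe_ids, columns=sample_ids)
    calls_arr = _detection_calls(values.to_numpy(), rng, config.call_center,
                                 config.call_scale, config.marginal_band)
    calls = pd.DataFrame(calls_arr, index=probe_ids, columns=sample_ids)
    bundle = ExpressionBundle(values=values, calls=calls)
    design = DesignTable(table=pd.DataFrame(design_rows))
    truth = GroundTruth(perturbations={c.condition_id: dict(c.deltas)
                                       for c in config.conditions})
    return bundle, design, collection, truth


# ---------------------------------------------------------------------------
# Feature-level (GGM) generator
# ---------------------------------------------------------------------------

def _check_spd(matrix: np.ndarray) -> None:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError("precision matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("precision matrix is not positive definite") from exc


def random_sparse_precision(p: int, n_edges: int,
                            weight_range: tuple[float, float] = (0.2, 0.4),
                            seed: int = 0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Random sparse SPD precision matrix with unit diagonal.

    Edge weights get uniform magnitudes in ``weight_range`` with random
    signs; positive definiteness is restored by shifting the diagonal past
    the most negative eigenvalue (margin 0.1) and re-standardizing to unit
    diagonal, which preserves the sparsity pattern exactly.
    """
    n_pairs = p * (p - 1) // 2
    if not 0 <= n_edges <= n_pairs:
        raise ConfigError(f"n_edges must be in [0, {n_pairs}]")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = [pairs[k] for k in sorted(rng.choice(n_pairs, size=n_edges, replace=False))]
    omega = np.eye(p)
    lo, hi = weight_range
    for i, j in chosen:
        w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        omega[i, j] = omega[j, i] = w
    min_eig = float(np.linalg.eigvalsh(omega).min())
    if min_eig < 0.1:
        omega += (0.1 - min_eig) * np.eye(p)
    d = np.sqrt(np.diag(omega))
    omega = omega / np.outer(d, d)
    _check_spd(omega)
    return omega, chosen


def population_pcor(precision: np.ndarray) -> np.ndarray:
    """Exact partial correlations implied by a precision matrix."""
    omega = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def simulate_features(n_conditions: int, precision: np.ndarray, seed: int = 0,
                      n_phenotypes: int = 0,
                      feature_names: list[str] | None = None
                      ) -> tuple[ScoreTable, PhenotypeTable, GroundTruth]:
    """Draw condition rows i.i.d. from N(0, precision^-1).

    The first ``p - n_phenotypes`` features are emitted as a gene-set score
    table, the rest as a phenotype table, so the pair exercises the same
    joint estimation path as real data.  True edges are the nonzero
    off-diagonal precision entries.
    """
    _check_spd(precision)
    p = precision.shape[0]
    if not 0 <= n_phenotypes < p:
        raise ConfigError("n_phenotypes must leave at least one gene-set feature")
    if n_conditions < 3:
        raise ConfigError("need at least 3 conditions")
    if feature_names is None:
        n_sets = p - n_phenotypes
        feature_names = ([f"set_{i + 1:02d}" for i in range(n_sets)]
                         + [f"pheno_{i + 1:02d}" for i in range(n_phenotypes)])
    if len(feature_names) != p:
        raise ConfigError("feature_names length must match precision dimension")
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(precision)
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((n_conditions, p)) @ chol.T
    conditions = [f"cond_{i + 1:03d}" for i in range(n_conditions)]
    frame = pd.DataFrame(x, index=conditions, columns=feature_names)
    n_sets = p - n_phenotypes
    scores = ScoreTable(scores=frame.iloc[:, :n_sets].T, method="dscore")
    phenos = PhenotypeTable(table=frame.iloc[:, n_sets:])
    edges = [(feature_names[i], feature_names[j])
             for i in range(p) for j in range(i + 1, p)
             if precision[i, j] != 0.0]
    truth = GroundTruth(precision=np.asarray(precision, dtype=float),
                        feature_names=list(feature_names), edges=edges)
    return scores, phenos, truth


# ---------------------------------------------------------------------------
# Bromobenzene-like case study
# ---------------------------------------------------------------------------

#: Named biomarker themes of the hepatotoxic time course; remaining sets are
#: unperturbed bystanders.
CASE_STUDY_SETS = (
    "glutathione_depletion",
    "dna_damage",
    "oxidative_stress",
    "inflammation",
    "glutathione_homeostasis",
    "cholesterol_synthesis",
    "glycolysis",
)

#: Planted log2-effect schedule over the four harvest timepoints (hours):
#: glutathione depletion and DNA damage dominate at 6 h, oxidative stress and
#: inflammation rise at 12 h alongside feedback glutathione synthesis, and at
#: 24 h inflammation peaks while energy-metabolism sets are suppressed.
CASE_STUDY_SCHEDULE: dict[float, dict[str, float]] = {
    2.0: {},
    6.0: {"glutathione_depletion": 1.8, "dna_damage": 1.5},
    12.0: {"oxidative_stress": 1.6, "inflammation": 1.4,
           "glutathione_homeostasis": 1.2, "glutathione_depletion": 1.0,
           "dna_damage": 0.8},
    24.0: {"inflammation": 2.2, "dna_damage": 1.6, "oxidative_stress": 1.0,
           "glutathione_homeostasis": 1.0, "cholesterol_synthesis": -1.2,
           "glycolysis": -1.0},
}


def case_study_config(seed: int = 0, n_sets: int = 58) -> SimulationConfig:
    """Configuration of the four-timepoint hepatotoxicant time course."""
    if n_sets < len(CASE_STUDY_SETS):
        raise ConfigError(f"case study needs at least {len(CASE_STUDY_SETS)} sets")
    names = list(CASE_STUDY_SETS) + [
        f"set_{i + 1:02d}" for i in range(n_sets - len(CASE_STUDY_SETS))
    ]
    conditions = [
        ConditionSpec(condition_id=f"BBz_{int(tp)}h", deltas=dict(deltas),
                      compound="bromobenzene_like", dose="300mg/kg",
                      timepoint_h=tp)
        for tp, deltas in CASE_STUDY_SCHEDULE.items()
    ]
    return SimulationConfig(n_sets=n_sets, set_names=names,
                            conditions=conditions, seed=seed)


def simulate_case_study(seed: int = 0, out_dir: str | Path | None = None
                        ) -> tuple[ExpressionBundle, DesignTable,
                                   GeneSetCollection, GroundTruth]:
    """Generate the hepatotoxicant time-course fixture (optionally on disk).

    When ``out_dir`` is given, writes expression.tsv, calls.tsv, design.tsv,
    sets.gmt, schedule.tsv and truth.yaml in the package's TSV/GMT dialects.
    """
    config = case_study_config(seed=seed)
    bundle, design, sets, truth = simulate_expression(config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tgx_io.write_expression(bundle, out_dir / "expression.tsv", out_dir / "calls.tsv")
        tgx_io.write_design(design, out_dir / "design.tsv")
        tgx_io.write_gmt(sets, out_dir / "sets.gmt")
        schedule = pd.DataFrame(
            [(c.condition_id, s, d) for c in config.conditions
             for s, d in c.deltas.items()],
            columns=["condition_id", "gene_set", "delta_log2"])
        with open(out_dir / "schedule.tsv", "w", encoding="utf-8", newline="\n") as fh:
            schedule.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        truth.to_yaml(out_dir / "truth.yaml")
    return bundle, design, sets, truth
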