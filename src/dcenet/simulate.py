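"""Synthetic repeated-measures expression studies with planted co-expression modules.

The generator emulates the structure the within-individual correlation stage
detects: groups of genes riding a shared latent trajectory per individual
(some with mirrored sign), against a background of flat noise-level genes,
plus Y-chromosome genes expressed only in males (the negative control the
background filter keys on). Every gene's role is recorded as ground truth so
downstream stages can be scored.

Latent model, per module m active in a group and per individual i:

    z_i(1) = 0
    z_i(t+1) = z_i(t) + shift_t + e,   e ~ Normal(0, 1)

with shift_1 = the module's ``trajectory_shift`` (the group-level mean log2
change between the first two time points) and shift_t = 0 afterwards. A
member gene g then reads

    x_g(i, t) = baseline_g + sign_g * loading * z_i(t) + Normal(0, noise_sd).

One RNG stream per study, consumed in a fixed documented order (module-gene
baselines, Y-gene baselines, trajectories by group/individual/module,
observation noise), so studies are bit-reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CoexpressionNetwork, ExpressionMatrix, canonical_edge
from . import io as dio


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    negative_fraction of the member genes load with mirrored (negative) sign;
    loading is the signal amplitude in log2 units; trajectory_shift the
    group-level mean log2 change from time point 1 to 2.
    """

    name: str
    n_genes: int
    groups: tuple[str, ...]
    negative_fraction: float = 0.25
    loading: float = 1.0
    trajectory_shift: float = -1.0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a module needs at least 2 genes")
        if not self.groups:
            raise ValueError("a module must be active in at least one group")
        if not 0 <= self.negative_fraction <= 1:
            raise ValueError("negative_fraction must be in [0, 1]")
        if self.loading <= 0:
            raise ValueError("loading must be positive")


@dataclass(frozen=True)
class StudySpec:
    """Full description of a synthetic study; all expression units are log2."""

    groups: tuple[tuple[str, int], ...]  # (label, individuals per group)
    modules: tuple[ModuleSpec, ...]
    n_timepoints: int = 3
    n_background_genes: int = 200
    n_y_genes: int = 20
    female_fraction: float = 0.5
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    background_level: float = 4.0
    # Y probes in females sit slightly above the raw noise floor
    # (cross-hybridization residue); keeps the filter threshold above
    # the background genes' own median.
    y_female_offset: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_background_genes < 0 or self.n_y_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        for g, n in self.groups:
            if n <= 0:
                raise ValueError(f"group {g!r} declared with zero individuals")
        for m in self.modules:
            unknown = set(m.groups) - set(labels)
            if unknown:
                raise ValueError(f"module {m.name!r} references unknown group(s) {sorted(unknown)}")

    @property
    def group_labels(self) -> list[str]:
        return [g for g, _ in self.groups]


@dataclass
class StudyTruth:
    """Ground truth of a generated study: roles, signs and planted edges."""

    role: dict[str, str] = field(default_factory=dict)  # gene -> module name | "background" | "Y"
    sign: dict[str, int] = field(default_factory=dict)
    module_genes: dict[str, list[str]] = field(default_factory=dict)
    module_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    shared_edges: set[tuple[str, str]] = field(default_factory=set)

    def module_labels(self, genes) -> list[str]:
        """Module membership label per gene (for comparing clusterings)."""
        return [self.role[g] for g in genes]

    def to_json(self, path) -> None:
        payload = {
            "role": self.role,
            "sign": self.sign,
            "module_genes": self.module_genes,
            "module_groups": {m: list(g) for m, g in self.module_groups.items()},
            "planted_edges": {g: sorted(map(list, e)) for g, e in self.planted_edges.items()},
            "shared_edges": sorted(map(list, self.shared_edges)),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "StudyTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            role=payload["role"],
            sign={g: int(s) for g, s in payload["sign"].items()},
            module_genes=payload["module_genes"],
            module_groups={m: tuple(g) for m, g in payload["module_groups"].items()},
            planted_edges={g: {tuple(e) for e in edges} for g, edges in payload["planted_edges"].items()},
            shared_edges={tuple(e) for e in payload["shared_edges"]},
        )


def default_study_spec(seed: int = 42) -> StudySpec:
    """The package's reference study: 2 groups x 12 individuals, 3 time points,
    five 8-gene modules (three shared, one unique per group), 200 background
    and 20 Y-chromosome genes."""
    shared = [ModuleSpec(f"M{i}", 8, ("LCD", "VLCD")) for i in (1, 2, 3)]
    unique = [ModuleSpec("M4_LCD", 8, ("LCD",)), ModuleSpec("M5_VLCD", 8, ("VLCD",))]
    return StudySpec(
        groups=(("LCD", 12), ("VLCD", 12)),
        modules=tuple(shared + unique),
        seed=seed,
    )


def study_spec_from_dict(payload: dict) -> StudySpec:
    """Build a StudySpec from a plain dict (e.g. parsed YAML).

    ``groups`` may be a mapping {label: n_individuals} or a list of pairs;
    ``modules`` is a list of ModuleSpec field dicts. Omitted fields fall back
    to the StudySpec defaults.
    """
    payload = dict(payload)
    groups = payload.pop("groups")
    if isinstance(groups, dict):
        groups = tuple(groups.items())
    else:
        groups = tuple((g, int(n)) for g, n in groups)
    modules = tuple(
        ModuleSpec(**{**m, "groups": tuple(m["groups"])}) for m in payload.pop("modules")
    )
    return StudySpec(groups=groups, modules=modules, **payload)


def _assign_sexes(spec: StudySpec) -> dict[str, str]:
    """Per group, the first round(f*n) individuals are female; >=1 female overall."""
    sexes: dict[str, str] = {}
    total_f = 0
    for grp, n in spec.groups:
        n_f = int(round(spec.female_fraction * n))
        for i in range(n):
            ind = f"{grp}{i + 1:02d}"
            sexes[ind] = "female" if i < n_f else "male"
        total_f += n_f
    if total_f == 0 and spec.female_fraction > 0:
        first = next(iter(sexes))
        sexes[first] = "female"
        total_f = 1
    if total_f == 0 and spec.n_y_genes > 0:
        raise ValueError("female_fraction yields zero females while n_y_genes > 0")
    return sexes


def generate_study(spec: StudySpec) -> tuple[ExpressionMatrix, dict[str, str], StudyTruth]:
    """Generate one synthetic study; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    T = spec.n_timepoints

    module_gene_ids: list[str] = []
    truth = StudyTruth()
    for m in spec.modules:
        genes = [f"{m.name}_{j:02d}" for j in range(m.n_genes)]
        truth.module_genes[m.name] = genes
        truth.module_groups[m.name] = m.groups
        n_neg = int(round(m.negative_fraction * m.n_genes))
        for j, g in enumerate(genes):
            truth.role[g] = m.name
            truth.sign[g] = -1 if j < n_neg else 1
        module_gene_ids.extend(genes)
    bg_genes = [f"BG_{i:04d}" for i in range(spec.n_background_genes)]
    y_genes = [f"Y_{i:02d}" for i in range(spec.n_y_genes)]
    for g in bg_genes:
        truth.role[g], truth.sign[g] = "background", 1
    for g in y_genes:
        truth.role[g], truth.sign[g] = "Y", 1

    all_labels = set(spec.group_labels)
    for grp in spec.group_labels:
        planted: set[tuple[str, str]] = set()
        for m in spec.modules:
            if grp not in m.groups:
                continue
            genes = truth.module_genes[m.name]
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    planted.add(canonical_edge(genes[i], genes[j]))
        truth.planted_edges[grp] = planted
    for m in spec.modules:
        if set(m.groups) == all_labels:
            genes = truth.module_genes[m.name]
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    truth.shared_edges.add(canonical_edge(genes[i], genes[j]))

    sexes = _assign_sexes(spec)

    # RNG draw order: module-gene baselines, Y baselines, trajectories, noise.
    baselines = dict(zip(module_gene_ids, rng.normal(spec.baseline_mean, spec.baseline_sd, len(module_gene_ids))))
    y_baselines = dict(zip(y_genes, rng.normal(spec.baseline_mean, spec.baseline_sd, len(y_genes))))

    trajectories: dict[tuple[str, str], np.ndarray] = {}  # (individual, module) -> z(t)
    sample_rows = []
    for grp, n in spec.groups:
        for i in range(n):
            ind = f"{grp}{i + 1:02d}"
            for m in spec.modules:
                if grp not in m.groups:
                    continue
                z = np.zeros(T)
                steps = rng.normal(0.0, 1.0, T - 1)
                for t in range(1, T):
                    shift = m.trajectory_shift if t == 1 else 0.0
                    z[t] = z[t - 1] + shift + steps[t - 1]
                trajectories[(ind, m.name)] = z
            for t in range(1, T + 1):
                sample_rows.append(
                    {"sample_id": f"{ind}_T{t}", "individual_id": ind, "group": grp,
                     "timepoint": t, "sex": sexes[ind]}
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    gene_ids = module_gene_ids + bg_genes + y_genes
    n_samples = len(samples)
    noise = rng.normal(0.0, spec.noise_sd, (len(gene_ids), n_samples))

    values = np.empty((len(gene_ids), n_samples))
    ind_of = samples["individual_id"].to_numpy()
    grp_of = samples["group"].to_numpy()
    tp_of = samples["timepoint"].to_numpy()
    sex_of = samples["sex"].to_numpy()
    for gi, g in enumerate(gene_ids):
        role = truth.role[g]
        if role == "background":
            values[gi] = spec.background_level
        elif role == "Y":
            male = sex_of == "male"
            values[gi] = np.where(male, y_baselines[g], spec.background_level + spec.y_female_offset)
        else:
            mod = role
            active = truth.module_groups[mod]
            base = baselines[g]
            row = np.full(n_samples, base)
            for si in range(n_samples):
                if grp_of[si] in active:
                    z = trajectories[(ind_of[si], mod)]
                    row[si] = base + truth.sign[g] * _module_loading(spec, mod) * z[tp_of[si] - 1]
            values[gi] = row
    values += noise

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples.index), samples)
    chrom = {g: ("Y" if truth.role[g] == "Y" else "1") for g in gene_ids}
    return expr, chrom, truth


def _module_loading(spec: StudySpec, name: str) -> float:
    for m in spec.modules:
        if m.name == name:
            return m.loading
    raise KeyError(name)


def truth_edge_metrics(net: CoexpressionNetwork, truth: StudyTruth,
                       scope: str = "group", group: str | None = None) -> dict[str, float]:
    """Recall and false-edge rate of a network against the planted edges.

    recall = |edges ∩ planted| / |planted|;
    false_edge_rate = |edges \\ planted| / |edges| (0 for an empty network).
    ``scope`` "group" scores against one group's planted set (``group``
    required); "shared" scores against the edges of modules active in every
    group.
    """
    if scope == "group":
        if group is None:
            raise ValueError("scope='group' needs a group label")
        planted = truth.planted_edges[group]
    elif scope == "shared":
        planted = truth.shared_edges
    else:
        raise ValueError(f"unknown scope {scope!r}")
    edges = net.edge_set()
    recall = len(edges & planted) / len(planted) if planted else 0.0
    false_rate = len(edges - planted) / len(edges) if edges else 0.0
    return {"recall": recall, "false_edge_rate": false_rate}


def write_study(spec: StudySpec, out_dir) -> dict[str, Path]:
    """Generate and write expression TSV, sample sheet, chromosome map, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, chrom, truth = generate_study(spec)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "chromosomes": out / "chromosomes.tsv",
        "truth": out / "truth.json",
    }
    dio.write_expression(expr, paths["expression"], paths["samples"])
    dio.write_chromosome_map(chrom, paths["chromosomes"])
    truth.to_json(paths["truth"])
    return paths
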