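"""Synthetic longitudinal Parkinson's-style cohorts with planted causal truth.

The generator emulates the shape of a de-novo PD observational cohort: annual
visits over years 0-7, baseline motor/non-motor scales, key SNPs plus
background SNPs, DAT-imaging variables on an offset month schedule, and
longitudinal outcomes (MoCA from year 4, UPDRS III from year 5).  Outcomes are
produced by a linear-Gaussian structural-equation network whose edge list and
coefficients are fully known, so structure learners and perturbation tests
downstream can be scored against ground truth.

Two kinds of planted effect exist:

* *level* edges — ``child = intercept + sum(coef * parent) + noise`` applied
  per visit year of the child;
* *slope modifiers* — ``(predictor x (year - first_year))`` interaction terms
  that change an outcome's rate of progression without moving its starting
  level.

Missingness is injected completely at random (MCAR) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortFrame, make_column, split_column
from .genotypes import GenotypeMatrix, encode_snps

__all__ = [
    "VariableSpec", "SNPSpec", "ImagingSpec", "PlantedEdge", "SlopeModifier",
    "CohortConfig", "RawCohort", "generate_cohort", "inject_missingness",
    "ground_truth_edges", "frame_from_raw", "default_cohort_config",
    "null_cohort_config", "chain_config", "full_demo_config", "write_cohort",
]


@dataclass(frozen=True)
class VariableSpec:
    """One clinical variable: time-invariant (``times=None``) or per-visit."""

    name: str
    role: str  # baseline | outcome | intervention
    times: tuple[int, ...] | None = None
    mean: float = 0.0
    noise_sd: float = 1.0
    lower: float | None = None
    upper: float | None = None
    integer: bool = False


@dataclass(frozen=True)
class SNPSpec:
    name: str
    maf: float
    key: bool = True
    #: inbreeding coefficient; 0 = Hardy-Weinberg equilibrium, >0 plants
    #: excess homozygosity so the HWE QC filter's rejection path is testable
    inbreeding: float = 0.0


@dataclass(frozen=True)
class ImagingSpec:
    """Per-participant random line: value(t months) = a_i + b_i * t/12 + noise."""

    name: str
    intercept_mean: float = 1.4
    intercept_sd: float = 0.3
    slope_mean: float = -0.06  # per year
    slope_sd: float = 0.03
    noise_sd: float = 0.02


@dataclass(frozen=True)
class PlantedEdge:
    """Level effect.  ``child`` may be ``"var"`` (applies at every visit of a
    time-varying variable) or ``"var@t"``; parents likewise."""

    parent: str
    child: str
    coefficient: float


@dataclass(frozen=True)
class SlopeModifier:
    """``predictor`` shifts ``outcome``'s per-year slope by ``per_year`` per
    unit of predictor, anchored at the outcome's first visit year."""

    predictor: str
    outcome: str
    per_year: float


@dataclass
class CohortConfig:
    n_participants: int
    variables: list[VariableSpec] = field(default_factory=list)
    snps: list[SNPSpec] = field(default_factory=list)
    imaging: list[ImagingSpec] = field(default_factory=list)
    visit_years: tuple[int, ...] = tuple(range(8))
    imaging_times_months: tuple[int, ...] = (0, 22)
    edges: list[PlantedEdge] = field(default_factory=list)
    slope_modifiers: list[SlopeModifier] = field(default_factory=list)
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    # ------------------------------------------------------------------
    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def nodes_of(self, name: str) -> list[str]:
        """Resolved node ids for a variable or SNP name."""
        if any(s.name == name for s in self.snps):
            return [name]
        v = self.variable(name)
        if v.times is None:
            return [name]
        return [make_column(v.name, t) for t in v.times]

    def _resolve(self, ref: str, as_child: bool = False) -> list[str]:
        var, t = split_column(ref)
        nodes = self.nodes_of(var)
        if t is None:
            return nodes
        node = make_column(var, t)
        if node not in nodes:
            raise ValueError(f"{ref!r} references an undeclared visit")
        return [node]

    def resolved_edges(self) -> list[tuple[str, str, float, str]]:
        """Planted effects expanded to (parent_node, child_node, coef, kind).

        Level edges keep their configured coefficient; slope modifiers expand
        to one edge per outcome visit with coefficient
        ``per_year * (t - first_visit)`` (zero-coefficient first-visit terms
        are omitted).  Order is stable: config order, then visit order.
        """
        out: list[tuple[str, str, float, str]] = []
        for e in self.edges:
            parents = self._resolve(e.parent)
            children = self._resolve(e.child)
            if len(parents) not in (1, len(children)):
                raise ValueError(
                    f"edge {e}: time-varying parent must be given an explicit visit")
            for i, child in enumerate(children):
                parent = parents[0] if len(parents) == 1 else parents[i]
                out.append((parent, child, e.coefficient, "level"))
        for m in self.slope_modifiers:
            (pred,) = self._resolve(m.predictor)
            v = self.variable(m.outcome)
            if v.times is None or len(v.times) < 2:
                raise ValueError(f"slope modifier target {m.outcome!r} needs >=2 visits")
            t0 = min(v.times)
            for t in v.times:
                if t != t0:
                    out.append((pred, make_column(m.outcome, t),
                                m.per_year * (t - t0), "slope"))
        return out

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for s in self.snps:
            g.add_node(s.name)
        for v in self.variables:
            g.add_nodes_from(self.nodes_of(v.name))
        for parent, child, coef, kind in self.resolved_edges():
            if parent not in g or child not in g:
                raise ValueError(f"edge references undeclared node: {parent}->{child}")
            g.add_edge(parent, child)
        return g

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        names = [v.name for v in self.variables] + [s.name for s in self.snps] \
            + [im.name for im in self.imaging]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for s in self.snps:
            if not 0.0 < s.maf < 1.0:
                raise ValueError(f"MAF for {s.name} must be in (0, 1), got {s.maf}")
        for v in self.variables:
            if not v.noise_sd > 0:
                raise ValueError(f"noise_sd for {v.name} must be > 0")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missingness rate for {name} must be in [0, 1)")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"planted graph has a cycle: {cycle}")

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(
            n_participants=d["n_participants"],
            variables=[VariableSpec(**v) if not isinstance(v, VariableSpec) else v
                       for v in d.get("variables", [])],
            snps=[SNPSpec(**s) if not isinstance(s, SNPSpec) else s
                  for s in d.get("snps", [])],
            imaging=[ImagingSpec(**i) if not isinstance(i, ImagingSpec) else i
                     for i in d.get("imaging", [])],
            visit_years=tuple(d.get("visit_years", range(8))),
            imaging_times_months=tuple(d.get("imaging_times_months", (0, 22))),
            edges=[PlantedEdge(**e) if not isinstance(e, PlantedEdge) else e
                   for e in d.get("edges", [])],
            slope_modifiers=[SlopeModifier(**m) if not isinstance(m, SlopeModifier)
                             else m for m in d.get("slope_modifiers", [])],
            missingness=dict(d.get("missingness", {})),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _postprocess(values: np.ndarray, spec: VariableSpec) -> np.ndarray:
    if spec.integer:
        values = np.round(values)
    if spec.lower is not None or spec.upper is not None:
        values = np.clip(values, spec.lower, spec.upper)
    return values


@dataclass
class RawCohort:
    """Generator output: long clinical/imaging tables + genotypes + truth."""

    clinical: pd.DataFrame  # participant_id, visit_year, variable, value
    genotypes: GenotypeMatrix
    imaging: pd.DataFrame  # participant_id, time_months, variable, value
    truth: pd.DataFrame  # parent, child, coefficient, kind
    config: CohortConfig

    @property
    def participants(self) -> list:
        return list(self.genotypes.participants)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> RawCohort:
    """Draw one cohort from the planted linear-Gaussian structural model.

    Genotypes are binomial(2, MAF) per SNP (optionally with planted excess
    homozygosity), baseline variables Gaussian, and time-indexed outcomes are
    generated in topological order of the planted graph.  Deterministic given
    ``seed`` (defaults to ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    participants = [f"P{i:04d}" for i in range(n)]

    # genotypes ---------------------------------------------------------
    dosage_cols = []
    for s in config.snps:
        p, f = s.maf, s.inbreeding
        probs = np.array([
            (1 - p) ** 2 + f * p * (1 - p),   # 0 copies of minor allele
            2 * p * (1 - p) * (1 - f),        # 1
            p ** 2 + f * p * (1 - p),         # 2
        ])
        dosage_cols.append(rng.choice(3, size=n, p=probs / probs.sum()).astype(float))
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((n, 0))
    genotypes = GenotypeMatrix(
        dosages=dosages,
        snp_names=[s.name for s in config.snps],
        participants=participants,
        key_flags=np.array([s.key for s in config.snps], dtype=bool),
    )

    # structural equations ---------------------------------------------
    values: dict[str, np.ndarray] = {
        s.name: genotypes.dosages[:, j] for j, s in enumerate(config.snps)
    }
    edges = config.resolved_edges()
    incoming: dict[str, list[tuple[str, float]]] = {}
    for parent, child, coef, _ in edges:
        incoming.setdefault(child, []).append((parent, coef))
    graph = config.graph()
    for node in nx.topological_sort(graph):
        if node in values:  # SNP
            continue
        var, _t = split_column(node)
        spec = config.variable(var)
        x = np.full(n, spec.mean) + rng.normal(0.0, spec.noise_sd, size=n)
        for parent, coef in incoming.get(node, []):
            x = x + coef * values[parent]
        values[node] = _postprocess(x, spec)

    clinical_rows = []
    for v in config.variables:
        for node in config.nodes_of(v.name):
            _, t = split_column(node)
            clinical_rows.append(pd.DataFrame({
                "participant_id": participants,
                "visit_year": t if t is not None else pd.NA,
                "variable": v.name,
                "value": values[node],
            }))
    clinical = (pd.concat(clinical_rows, ignore_index=True) if clinical_rows
                else pd.DataFrame(columns=["participant_id", "visit_year",
                                           "variable", "value"]))

    # imaging: participant-level random intercept + slope lines ---------
    imaging_rows = []
    for im in config.imaging:
        a = rng.normal(im.intercept_mean, im.intercept_sd, size=n)
        b = rng.normal(im.slope_mean, im.slope_sd, size=n)
        for month in config.imaging_times_months:
            y = a + b * (month / 12.0) + rng.normal(0.0, im.noise_sd, size=n)
            imaging_rows.append(pd.DataFrame({
                "participant_id": participants,
                "time_months": month,
                "variable": im.name,
                "value": y,
            }))
    imaging = (pd.concat(imaging_rows, ignore_index=True) if imaging_rows
               else pd.DataFrame(columns=["participant_id", "time_months",
                                          "variable", "value"]))

    truth = pd.DataFrame(edges, columns=["parent", "child", "coefficient", "kind"])
    cohort = RawCohort(clinical=clinical, genotypes=genotypes, imaging=imaging,
                       truth=truth, config=config)
    if any(rate > 0 for rate in config.missingness.values()):
        cohort = inject_missingness(cohort, config.missingness,
                                    seed=rng.integers(2 ** 31))
    return cohort


def inject_missingness(cohort: RawCohort, rates: dict[str, float],
                       seed: int = 0) -> RawCohort:
    """Delete entries completely at random at per-variable ``rates``.

    Rates are keyed by clinical/imaging variable name or SNP name.  Deletion
    is independent of all values (MCAR); surviving entries are unchanged.
    Deterministic given ``seed``.
    """
    for name, rate in rates.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missingness rate for {name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    clinical = cohort.clinical.copy()
    for name, rate in rates.items():
        if rate == 0:
            continue
        sel = (clinical["variable"] == name).to_numpy()
        hit = rng.random(sel.sum()) < rate
        idx = clinical.index[sel][hit]
        clinical.loc[idx, "value"] = np.nan
    dosages = cohort.genotypes.dosages.copy()
    for j, name in enumerate(cohort.genotypes.snp_names):
        rate = rates.get(name, 0.0)
        if rate > 0:
            hit = rng.random(dosages.shape[0]) < rate
            dosages[hit, j] = np.nan
    imaging = cohort.imaging.copy()
    for name, rate in rates.items():
        if rate == 0 or imaging.empty:
            continue
        sel = (imaging["variable"] == name).to_numpy()
        hit = rng.random(sel.sum()) < rate
        idx = imaging.index[sel][hit]
        imaging.loc[idx, "value"] = np.nan
    return RawCohort(clinical=clinical,
                     genotypes=replace(cohort.genotypes, dosages=dosages),
                     imaging=imaging, truth=cohort.truth, config=cohort.config)


def ground_truth_edges(config: CohortConfig) -> pd.DataFrame:
    """The planted (parent, child, coefficient) triples, slope terms flagged."""
    config.validate()
    return pd.DataFrame(config.resolved_edges(),
                        columns=["parent", "child", "coefficient", "kind"])


# ---------------------------------------------------------------------------
def frame_from_raw(cohort: RawCohort, code_snps: bool = True) -> CohortFrame:
    """Assemble a complete :class:`CohortFrame` directly from generator output.

    Bypasses QC/imputation and therefore requires a cohort without injected
    missingness; intended for simulation studies on known-complete data.  Key
    SNPs are expanded into additive/dominant/recessive coding columns.
    """
    clin = cohort.clinical
    if clin["value"].isna().any() or np.any(cohort.genotypes.missing_mask):
        raise ValueError("cohort has missing entries; run the preprocess pipeline")
    wide = {}
    roles = {}
    cfg = cohort.config
    for v in cfg.variables:
        sub = clin[clin["variable"] == v.name]
        for node in cfg.nodes_of(v.name):
            _, t = split_column(node)
            if t is None:
                rows = sub.set_index("participant_id")["value"]
            else:
                rows = sub[sub["visit_year"] == t].set_index("participant_id")["value"]
            wide[node] = rows.reindex(cohort.participants).to_numpy()
            roles[node] = v.role
    data = pd.DataFrame(wide, index=cohort.participants)
    snp_group: dict[str, str] = {}
    if code_snps and cohort.genotypes.n_snps:
        key_names = [s.name for s in cfg.snps if s.key]
        if key_names:
            coded = encode_snps(cohort.genotypes, key_names)
            for col in coded.columns:
                roles[col] = "genetic"
                snp_group[col] = col.rsplit("_", 1)[0]
            data = pd.concat([data, coded], axis=1)
    return CohortFrame(data=data, roles=roles, snp_group=snp_group)


# ---------------------------------------------------------------------------
# study configurations
# ---------------------------------------------------------------------------
def default_cohort_config(n_participants: int = 300, seed: int = 0,
                          missingness: float = 0.0) -> CohortConfig:
    """The default study cohort: planted predictors of PD outcome and progression.

    Emulates a de-novo PD cohort's marginal scales (age 59.6 +/- 8.5, S/E ADL
    93.1 +/- 5.2, UPDRS II 5.8 +/- 3.1; MoCA around 26.6) with planted
    standardized level effects of ~0.58 (age and baseline S/E ADL on MoCA
    years 4-7; baseline UPDRS II on UPDRS III years 5-7) and a planted
    progression effect: each minor allele of the key SNP steepens MoCA decline
    by 0.4 points/year.
    """
    moca_sd, updrs3_sd = 2.0, 5.0
    b_age = -2.0 / 8.5      # standardized effect 2/sqrt(2*4+4) = 0.577
    b_adl = 2.0 / 5.2
    b_u2 = 3.5 / 3.1        # standardized effect 3.5/sqrt(3.5^2+25) = 0.573
    miss = {}
    if missingness > 0:
        miss = {v: missingness for v in ("se_adl", "updrs2", "moca", "updrs3", "bst1")}
    return CohortConfig(
        n_participants=n_participants,
        visit_years=tuple(range(8)),
        variables=[
            VariableSpec("age", "baseline", mean=59.6, noise_sd=8.5),
            VariableSpec("se_adl", "baseline", mean=93.1, noise_sd=5.2,
                         upper=100.0),
            VariableSpec("updrs2", "baseline", mean=5.8, noise_sd=3.1, lower=0.0),
            VariableSpec("moca", "outcome", times=(4, 5, 6, 7),
                         mean=26.6 + 14.02 - 35.81, noise_sd=moca_sd),
            VariableSpec("updrs3", "outcome", times=(5, 6, 7),
                         mean=21.5 - b_u2 * 5.8, noise_sd=updrs3_sd),
        ],
        snps=[SNPSpec("bst1", maf=0.35, key=True)],
        imaging=[],
        edges=[
            PlantedEdge("age", "moca", b_age),
            PlantedEdge("se_adl", "moca", b_adl),
            PlantedEdge("updrs2", "updrs3", b_u2),
        ],
        slope_modifiers=[SlopeModifier("bst1", "moca", -0.4)],
        missingness=miss,
        seed=seed,
    )


def null_cohort_config(n_participants: int = 200, seed: int = 0) -> CohortConfig:
    """Null cohort for calibration studies: the candidate predictor ``x_pred``
    is independent of the endpoint ``y``, which is driven by ``z_cov`` only."""
    return CohortConfig(
        n_participants=n_participants,
        visit_years=(0, 4, 5, 6, 7),
        variables=[
            VariableSpec("x_pred", "baseline", mean=0.0, noise_sd=1.0),
            VariableSpec("z_cov", "baseline", mean=0.0, noise_sd=1.0),
            VariableSpec("y", "outcome", times=(4, 5, 6, 7), mean=10.0,
                         noise_sd=1.0),
        ],
        snps=[],
        edges=[PlantedEdge("z_cov", "y", 0.8)],
        seed=seed,
    )


def chain_config(beta1: float = 1.0, beta2: float = 1.0,
                 n_participants: int = 500, seed: int = 0) -> CohortConfig:
    """Three-node chain a -> b -> c used for closed-form propagation checks."""
    return CohortConfig(
        n_participants=n_participants,
        visit_years=(0, 1, 2),
        variables=[
            VariableSpec("a", "baseline", mean=0.0, noise_sd=1.0),
            VariableSpec("b", "outcome", times=(1,), mean=1.0, noise_sd=1.0),
            VariableSpec("c", "outcome", times=(2,), mean=-0.5, noise_sd=1.0),
        ],
        edges=[PlantedEdge("a", "b@1", beta1), PlantedEdge("b@1", "c@2", beta2)],
        seed=seed,
    )


def full_demo_config(n_participants: int = 300, seed: int = 0,
                     missingness: float = 0.03,
                     n_background_snps: int = 40) -> CohortConfig:
    """A richer cohort exercising the whole pipeline: extra baseline scales,
    an intervention series, imaging on the 0/22-month schedule, and background
    SNPs for the PCA stage."""
    base = default_cohort_config(n_participants=n_participants, seed=seed)
    rng = np.random.default_rng(12345)  # fixed: background MAFs are part of the design
    background = [SNPSpec(f"bg{j:03d}", maf=float(rng.uniform(0.1, 0.5)), key=False)
                  for j in range(n_background_snps)]
    extra_vars = [
        VariableSpec("mmse", "baseline", mean=29.4, noise_sd=1.1, upper=30.0),
        VariableSpec("updrs1", "baseline", mean=1.5, noise_sd=1.4, lower=0.0),
        VariableSpec("levodopa", "intervention", times=(5, 6, 7), mean=400.0,
                     noise_sd=150.0, lower=0.0),
    ]
    miss = {v.name: missingness for v in base.variables + extra_vars}
    miss.update({s.name: missingness for s in base.snps})
    return replace(
        base,
        variables=base.variables + extra_vars,
        snps=base.snps + background,
        imaging=[ImagingSpec("sbr")],
        missingness=miss if missingness > 0 else {},
    )


# ---------------------------------------------------------------------------
def write_cohort(cohort: RawCohort, out_dir: str | Path,
                 vcf: bool = False) -> dict[str, Path]:
    """Emit the cohort as plain-text tables.

    clinical.csv / imaging.csv in long format, genotypes.tsv with participants
    as rows and empty cells for missing calls, truth.csv with the planted
    edges, and optionally genotypes.vcf (diploid GT records).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["clinical"] = out / "clinical.csv"
    cohort.clinical.to_csv(paths["clinical"], index=False)
    paths["imaging"] = out / "imaging.csv"
    cohort.imaging.to_csv(paths["imaging"], index=False)
    paths["genotypes"] = out / "genotypes.tsv"
    gdf = cohort.genotypes.to_frame()
    gdf.to_csv(paths["genotypes"], sep="\t", index_label="participant_id",
               float_format="%.0f", na_rep="")
    paths["truth"] = out / "truth.csv"
    cohort.truth.to_csv(paths["truth"], index=False)
    paths["roles"] = out / "roles.yaml"
    roles = {v.name: v.role for v in cohort.config.variables}
    key_snps = [s.name for s in cohort.config.snps if s.key]
    paths["roles"].write_text(yaml.safe_dump(
        {"roles": roles, "key_snps": key_snps}, sort_keys=True))
    if vcf:
        paths["vcf"] = out / "genotypes.vcf"
        _write_vcf(cohort.genotypes, paths["vcf"])
    return paths


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "##contig=<ID=1>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(str(p) for p in g.participants)]
    for j, name in enumerate(g.snp_names):
        calls = ["./." if np.isnan(d) else _GT[int(d)] for d in g.dosages[:, j]]
        lines.append(f"1\t{j + 1}\t{name}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls))
    path.write_text("\n".join(lines) + "\n")
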