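"""End-to-end preprocessing: QC, imputation, codings, PCA, interpolation, assembly.

Stage order (fixed, logged in the QC report): SNP QC -> genotype imputation ->
clinical pruning -> clinical k-NN imputation -> SNP codings + genetic PCA ->
imaging interpolation -> participant matching and frame assembly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clinical import knn_impute, pivot_clinical, prune_clinical
from .cohort import CohortFrame, split_column
from .genotypes import (GenotypeMatrix, QCReport, encode_snps, genotype_pca,
                        impute_genotypes, snp_qc)
from .imaging import interpolate_imaging
from .synthetic import RawCohort

__all__ = [
    "read_genotypes_tsv", "read_vcf", "read_roles", "assemble_frame",
    "preprocess_tables", "preprocess_cohort",
]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------
def read_genotypes_tsv(path, key_snps=None) -> GenotypeMatrix:
    """Participant x SNP dosage TSV (0/1/2, empty cell = missing)."""
    df = pd.read_csv(path, sep="\t", index_col="participant_id")
    key_snps = set(key_snps or [])
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        snp_names=list(df.columns),
        participants=list(df.index.astype(str)),
        key_flags=np.array([c in key_snps for c in df.columns], dtype=bool)
        if key_snps else None,
    )


def read_vcf(path, key_snps=None) -> GenotypeMatrix:
    """Diploid GT records -> minor-allele dosage matrix (missing GT = NaN)."""
    from cyvcf2 import VCF  # optional dependency; only needed for VCF input

    vcf = VCF(str(path))
    participants = list(vcf.samples)
    names, rows = [], []
    for record in vcf:
        names.append(record.ID or f"{record.CHROM}:{record.POS}")
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        gt = np.asarray(record.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    key_snps = set(key_snps or [])
    return GenotypeMatrix(
        dosages=np.array(rows).T if rows else np.empty((len(participants), 0)),
        snp_names=names,
        participants=participants,
        key_flags=np.array([n in key_snps for n in names], dtype=bool)
        if key_snps else None,
    )


def read_roles(path) -> dict[str, str]:
    """Variable -> role mapping from a YAML/JSON metadata file."""
    meta = yaml.safe_load(Path(path).read_text())
    return dict(meta["roles"] if "roles" in meta else meta)


# ---------------------------------------------------------------------------
def assemble_frame(
    clinical: pd.DataFrame,
    roles: dict[str, str],
    genetic: pd.DataFrame | None = None,
    pcs: pd.DataFrame | None = None,
    imaging: pd.DataFrame | None = None,
    snp_group: dict[str, str] | None = None,
    imputed_clinical: pd.DataFrame | None = None,
    imputed_genetic: pd.DataFrame | None = None,
) -> CohortFrame:
    """Join the completed pieces on their shared participants.

    ``clinical`` is the wide, fully-imputed clinical table; ``roles`` maps
    clinical *variable* names to baseline/outcome/intervention.  Participants
    absent from any provided piece are dropped (intersection rule).
    """
    pieces = [("clinical", clinical)]
    if genetic is not None and len(genetic.columns):
        pieces.append(("genetic", genetic))
    if pcs is not None and len(pcs.columns):
        pieces.append(("genetic_pc", pcs))
    if imaging is not None and len(imaging.columns):
        pieces.append(("imaging", imaging))
    shared = None
    for _, df in pieces:
        idx = set(df.index)
        shared = idx if shared is None else shared & idx
    if not shared:
        raise ValueError("no participants shared across all input tables")
    order = [p for p in clinical.index if p in shared]

    col_roles: dict[str, str] = {}
    for col in clinical.columns:
        var, _ = split_column(col)
        if var not in roles:
            raise KeyError(f"no role declared for clinical variable {var!r}")
        col_roles[col] = roles[var]
    parts = [clinical.loc[order]]
    prov_parts = {}
    for kind, df in pieces[1:]:
        role = {"genetic": "genetic", "genetic_pc": "genetic_pc",
                "imaging": "imaging"}[kind]
        for col in df.columns:
            col_roles[col] = role
        parts.append(df.loc[order])
    data = pd.concat(parts, axis=1)
    if data.isna().any().any():
        bad = list(data.columns[data.isna().any()])
        raise ValueError(f"assembled frame has missing cells in {bad}")

    provenance = pd.DataFrame("observed", index=order, columns=data.columns)
    if imputed_clinical is not None:
        m = imputed_clinical.reindex(index=order, columns=clinical.columns)
        provenance.loc[:, clinical.columns] = np.where(
            m.fillna(False), "imputed", "observed")
    if imputed_genetic is not None and genetic is not None:
        m = imputed_genetic.reindex(index=order, columns=genetic.columns)
        provenance.loc[:, genetic.columns] = np.where(
            m.fillna(False), "imputed", "observed")
    if pcs is not None and len(pcs.columns):
        provenance.loc[:, pcs.columns] = "derived"
    if imaging is not None and len(imaging.columns):
        provenance.loc[:, imaging.columns] = "interpolated"
    return CohortFrame(data=data, roles=col_roles,
                       snp_group=dict(snp_group or {}), provenance=provenance)


def preprocess_tables(
    clinical: pd.DataFrame,
    genotypes: GenotypeMatrix | None,
    imaging: pd.DataFrame | None,
    roles: dict[str, str],
    n_components: int = 3,
    k_candidates=(1, 3, 5, 10),
    cv_folds: int = 5,
    knn_k_genotypes: int = 5,
    visit_years=None,
    seed: int = 0,
) -> tuple[CohortFrame, QCReport]:
    """Run the full preprocessing pipeline on raw long/matrix inputs."""
    report = QCReport()
    coded = pcs = None
    snp_group: dict[str, str] = {}
    imputed_genetic = None
    if genotypes is not None and genotypes.n_snps:
        g, snp_report = snp_qc(genotypes)
        report.snps = snp_report.snps
        was_missing = g.missing_mask.copy()
        g = impute_genotypes(g, k=knn_k_genotypes)
        key_names = [n for n, f in zip(g.snp_names, g.key_flags) if f]
        if key_names:
            coded = encode_snps(g, key_names)
            snp_group = {c: c.rsplit("_", 1)[0] for c in coded.columns}
            imputed_genetic = pd.DataFrame(False, index=coded.index,
                                           columns=coded.columns)
            for snp in key_names:
                j = g.snp_names.index(snp)
                for suffix in ("additive", "dominant", "recessive"):
                    imputed_genetic[f"{snp}_{suffix}"] = was_missing[:, j]
        n_background = int(np.sum(~g.key_flags))
        if n_background >= max(2, n_components):
            pcs = genotype_pca(g, n_components=min(n_components, n_background))

    pruned, clin_report = prune_clinical(clinical)
    report.variables = clin_report.variables
    report.participants = clin_report.participants
    missing_mask = pruned.isna()
    if missing_mask.any().any():
        complete, _k = knn_impute(pruned, k_candidates=k_candidates,
                                  cv_folds=cv_folds, seed=seed)
    else:
        complete = pruned

    imaging_wide = None
    if imaging is not None and len(imaging):
        if visit_years is None:
            times = sorted({t for c in complete.columns
                            for t in [split_column(c)[1]] if t is not None})
            visit_years = times or [0]
        imaging_wide = interpolate_imaging(imaging, visit_years)

    frame = assemble_frame(
        complete, roles, genetic=coded, pcs=pcs, imaging=imaging_wide,
        snp_group=snp_group, imputed_clinical=missing_mask,
        imputed_genetic=imputed_genetic,
    )
    return frame, report


def preprocess_cohort(raw: RawCohort, **kwargs) -> tuple[CohortFrame, QCReport]:
    """Preprocess a synthetic cohort, taking roles from its configuration."""
    roles = {v.name: v.role for v in raw.config.variables}
    visit_years = kwargs.pop("visit_years", raw.config.visit_years)
    return preprocess_tables(raw.clinical, raw.genotypes, raw.imaging, roles,
                             visit_years=visit_years, **kwargs)
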