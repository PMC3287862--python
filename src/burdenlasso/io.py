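"""Readers/writers for the pipeline's external formats.

Genotypes travel as VCF 4.2 (one record per biallelic variant, GT fields,
INFO tags ``GENE=<symbol>;ANNO=<ns|s>``) or as a delimited dosage matrix
with a sidecar variant-metadata table.  Covariates, phenotype replicates
(columns ``<trait>.<replicate>``), and the truth set are tab-delimited.
A ``manifest.yaml`` records files, seed and parameters for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .errors import ConfigurationError, ParseError
from .types import (
    NONSYNONYMOUS,
    SYNONYMOUS,
    GenotypeSet,
    ReplicateSet,
    TruthSet,
)

logger = logging.getLogger(__name__)

_ANNO_CODE = {NONSYNONYMOUS: "ns", SYNONYMOUS: "s"}
_ANNO_DECODE = {"ns": NONSYNONYMOUS, "s": SYNONYMOUS}


# ---------------------------------------------------------------------------
# VCF


def write_vcf(g: GenotypeSet, path) -> None:
    """Write genotypes as an uncompressed VCF with GENE/ANNO INFO tags.

    Dosage 0/1/2 maps to GT 0/0, 0/1, 1/1; the ALT allele is the stored
    minor allele by construction.
    """
    if not g.variant_ids:
        raise ConfigurationError("cannot write a VCF with no variants")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write(
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
        )
        fh.write(
            '##INFO=<ID=ANNO,Number=1,Type=String,'
            'Description="Functional annotation: ns or s">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, vid in enumerate(g.variant_ids):
            info = f"GENE={g.gene_of[vid]};ANNO={_ANNO_CODE[g.annotation_of[vid]]}"
            gts = "\t".join(gt_map[int(d)] for d in g.dosages[:, j])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tC\t.\tPASS\t{info}\tGT\t{gts}\n")


def _read_vcf(path) -> GenotypeSet:
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    variant_ids: list[str] = []
    gene_of: dict[str, str] = {}
    annotation_of: dict[str, str] = {}
    columns: list[np.ndarray] = []
    n_imputed = 0
    for rec in vcf:
        base_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gene = rec.INFO.get("GENE")
        anno = rec.INFO.get("ANNO")
        if gene is None or anno is None:
            raise ParseError(f"variant {base_id}: missing GENE/ANNO INFO tags")
        n_alt = len(rec.ALT)
        if n_alt <= 1:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(rec.gt_types)
            alt_counts = [np.where(gt == 3, 2, gt).astype(float)]
            missing_mask = gt == 2
            ids = [base_id]
        else:
            # split a multi-allelic site into one biallelic record per ALT
            alleles = np.asarray(rec.genotypes, dtype=object)[:, :2].astype(int)
            missing_mask = (alleles < 0).any(axis=1)
            alt_counts = [
                (alleles == k).sum(axis=1).astype(float) for k in range(1, n_alt + 1)
            ]
            ids = [f"{base_id}.{k}" for k in range(1, n_alt + 1)]
        for vid, dos in zip(ids, alt_counts):
            if missing_mask.any():
                frac = missing_mask.mean()
                if frac > 0.10:
                    logger.warning(
                        "variant %s: %.0f%% missing genotypes", vid, 100 * frac
                    )
                obs = dos[~missing_mask]
                fill = round(float(obs.mean())) if obs.size else 0
                dos = dos.copy()
                dos[missing_mask] = fill
                n_imputed += int(missing_mask.sum())
            variant_ids.append(vid)
            gene_of[vid] = gene
            annotation_of[vid] = _ANNO_DECODE.get(anno, anno)
            columns.append(dos)
    vcf.close()
    if n_imputed:
        logger.info("imputed %d missing genotypes to rounded per-variant means", n_imputed)
    dosages = np.column_stack(columns) if columns else np.empty((len(individuals), 0))
    return _finalize_genotypes(individuals, variant_ids, dosages, gene_of, annotation_of)


def _finalize_genotypes(individuals, variant_ids, dosages, gene_of, annotation_of):
    """Orient every column toward the sample minor allele and recompute MAF."""
    alt_freq = dosages.mean(axis=0) / 2.0 if dosages.size else np.empty(0)
    flip = alt_freq > 0.5
    dosages[:, flip] = 2 - dosages[:, flip]
    freq = dosages.mean(axis=0) / 2.0 if dosages.size else np.empty(0)
    maf = np.minimum(freq, 1.0 - freq)
    return GenotypeSet(
        individual_ids=list(individuals),
        variant_ids=variant_ids,
        dosages=dosages.astype(np.int8),
        gene_of=gene_of,
        annotation_of=annotation_of,
        maf=maf,
    )


def _read_matrix(path, metadata_path=None) -> GenotypeSet:
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_name("variants.tsv")
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t").set_index("variant")
    dosages = df.to_numpy(dtype=float)
    if np.isnan(dosages).any():
        for j in range(dosages.shape[1]):
            col = dosages[:, j]
            miss = np.isnan(col)
            if miss.any():
                if miss.mean() > 0.10:
                    logger.warning(
                        "variant %s: %.0f%% missing", df.columns[j], 100 * miss.mean()
                    )
                col[miss] = round(float(col[~miss].mean())) if (~miss).any() else 0
    gene_of = meta["gene"].to_dict()
    annotation_of = {
        v: _ANNO_DECODE.get(a, a) for v, a in meta["annotation"].to_dict().items()
    }
    return _finalize_genotypes(
        list(df.index), list(df.columns), dosages, gene_of, annotation_of
    )


def read_genotypes(path, format: str = "vcf", metadata_path=None) -> GenotypeSet:
    """Load a GenotypeSet from VCF or a delimited dosage matrix.

    Dosages are minor-allele counts with the minor allele determined from
    the sample; missing genotypes are imputed to the rounded per-variant
    mean dosage (logged).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path, metadata_path)
    raise ConfigurationError(f"unknown genotype format {format!r}")


def write_matrix(g: GenotypeSet, path, metadata_path=None) -> None:
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_name("variants.tsv")
    pd.DataFrame(g.dosages, index=g.individual_ids, columns=g.variant_ids).to_csv(
        path, sep="\t"
    )
    pd.DataFrame(
        {
            "variant": g.variant_ids,
            "gene": [g.gene_of[v] for v in g.variant_ids],
            "annotation": [_ANNO_CODE[g.annotation_of[v]] for v in g.variant_ids],
        }
    ).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tables


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index_label="individual")


def read_covariates(path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col="individual")
    if cov.isna().any().any():
        raise ParseError("missing covariate values are not allowed")
    return cov


def write_phenotypes(reps: ReplicateSet, path) -> None:
    """One column per trait.replicate (1-based replicate index)."""
    data = {}
    for trait, arr in reps.traits.items():
        for r in range(reps.R):
            data[f"{trait}.{r + 1}"] = arr[:, r]
    pd.DataFrame(data, index=reps.covariates.index).to_csv(
        path, sep="\t", index_label="individual"
    )


def read_phenotypes(path, covariates: pd.DataFrame) -> ReplicateSet:
    df = pd.read_csv(path, sep="\t", index_col="individual")
    traits: dict[str, dict[int, np.ndarray]] = {}
    for col in df.columns:
        try:
            trait, rep = col.rsplit(".", 1)
            rep_i = int(rep)
        except ValueError as exc:
            raise ParseError(f"phenotype column {col!r} is not <trait>.<replicate>") from exc
        traits.setdefault(trait, {})[rep_i] = df[col].to_numpy(dtype=float)
    arrays = {}
    R = None
    for trait, cols in traits.items():
        ordered = [cols[k] for k in sorted(cols)]
        arrays[trait] = np.column_stack(ordered)
        R = len(ordered) if R is None else R
        if len(ordered) != R:
            raise ParseError("traits have differing replicate counts")
    if list(df.index) != list(covariates.index):
        raise ParseError("phenotype individuals do not match covariates")
    return ReplicateSet(covariates=covariates, traits=arrays, R=R or 0)


def write_truth(truth: TruthSet, path) -> None:
    rows = []
    for trait, variants in truth.causal_variants.items():
        effects = truth.effect_sizes.get(trait, {})
        for v in sorted(variants):
            rows.append({"trait": trait, "variant": v, "effect": effects.get(v, np.nan)})
    pd.DataFrame(rows, columns=["trait", "variant", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path, g: GenotypeSet) -> TruthSet:
    df = pd.read_csv(path, sep="\t")
    truth = TruthSet()
    for trait, grp in df.groupby("trait"):
        variants = set(grp["variant"])
        truth.causal_variants[trait] = variants
        truth.causal_genes[trait] = {g.gene_of[v] for v in variants if v in g.gene_of}
        truth.effect_sizes[trait] = {
            r.variant: float(r.effect) for r in grp.itertuples() if np.isfinite(r.effect)
        }
    return truth


# ---------------------------------------------------------------------------
# dataset bundle + manifest


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_dataset(
    g: GenotypeSet,
    reps: ReplicateSet,
    truth: TruthSet,
    out_dir,
    seed: int | None = None,
    params: dict | None = None,
) -> dict:
    """Emit the full dataset bundle (VCF + TSV tables + manifest.yaml)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "genotypes": "genotypes.vcf",
        "covariates": "covariates.tsv",
        "phenotypes": "phenotypes.tsv",
        "truth": "truth.tsv",
    }
    write_vcf(g, out / files["genotypes"])
    write_covariates(reps.covariates, out / files["covariates"])
    write_phenotypes(reps, out / files["phenotypes"])
    write_truth(truth, out / files["truth"])
    manifest = {
        "files": files,
        "seed": seed,
        "parameters": params or {},
        "n_individuals": g.n_individuals,
        "n_variants": g.n_variants,
        "R": reps.R,
    }
    manifest["hash"] = config_hash(manifest)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_dataset(in_dir) -> tuple[GenotypeSet, ReplicateSet, TruthSet]:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    files = manifest["files"]
    g = read_genotypes(in_dir / files["genotypes"], "vcf")
    cov = read_covariates(in_dir / files["covariates"])
    reps = read_phenotypes(in_dir / files["phenotypes"], cov)
    truth = read_truth(in_dir / files["truth"], g)
    return g, reps, truth


# ---------------------------------------------------------------------------
# fit / report serialization


def write_fit_results(fits, path, manifest_path=None, seed=None, extra=None) -> None:
    """Coefficient table (feature, gene, class, coefficient, selected, replicate)."""
    rows = []
    for r, fit in enumerate(fits):
        cols = fit.design_columns.set_index("feature")
        for name, coef in fit.coefficients.items():
            rows.append(
                {
                    "replicate": r,
                    "feature": name,
                    "gene": cols.loc[name, "gene"],
                    "class": cols.loc[name, "penalty_class"],
                    "coefficient": coef,
                    "selected": bool(fit.selected[name]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if manifest_path is not None:
        info = {
            "n_replicates": len(fits),
            "seed": seed,
            "links": sorted({f.link for f in fits}),
            "cv_errors": [f.cv_error for f in fits],
            "converged": all(f.converged for f in fits),
        }
        if extra:
            info.update(extra)
        with open(manifest_path, "w") as fh:
            json.dump(info, fh, indent=2, default=float)
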