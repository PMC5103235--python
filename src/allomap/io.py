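"""Readers and writers for the formats the tool consumes and emits.

Genotypes come either from a VCF (progeny as samples, the two parents
optionally as designated samples used to classify segregation) or from a
plain TSV matrix (one row per SNP: snp_id, chrom, pos, optional seg_type,
then one 0/1/2/NA code column per progeny). Phenotypes are a long-format
CSV with columns progeny_id, trait, age, value (trait in {height,
diameter}) and an optional per-progeny h0 column or trait="h0" rows for
the establishment-year height; when absent, h0 defaults to 0 (the offset
is then absorbed into the fitted coefficients). Scan output is TSV.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from allomap.allometry import Establishment
from allomap.family_genetics import (
    MISSING,
    SegregationType,
    SnpRecord,
    classify_segregation,
)
from allomap.likelihood import LongitudinalTraitPair, MonotonicityWarning
from allomap.scan import ScanResult, manhattan_table, results_table

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes_csv",
    "write_results_tsv",
    "write_manhattan_tsv",
]


class InputFormatError(ValueError):
    """A malformed input file; the message names file, line/field, and value."""


# ---------------------------------------------------------------------------
# Genotypes


def _infer_seg_type(codes: np.ndarray, snp_id: str, path) -> SegregationType:
    observed = np.unique(codes[codes != MISSING])
    if observed.size >= 3:
        return SegregationType.INTERCROSS
    # two observed classes: 1:1 testcross unless both homozygote classes appear
    if observed.size == 2 and 0 in observed and 2 in observed:
        return SegregationType.INTERCROSS
    logger.debug("%s: inferring testcross segregation for %s", path, snp_id)
    return SegregationType.TESTCROSS


def read_genotypes_tsv(path: str | Path) -> list[SnpRecord]:
    """Read the SNP-by-progeny TSV matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = ["snp_id", "chrom", "pos"]
    for col in required:
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column '{col}'")
    meta = set(required) | {"seg_type"}
    progeny_cols = [c for c in df.columns if c not in meta]
    if not progeny_cols:
        raise InputFormatError(f"{path}: no progeny genotype columns found")
    snps = []
    codes_frame = df[progeny_cols].to_numpy()
    for r, row in df.iterrows():
        raw = codes_frame[r]
        codes = np.full(len(progeny_cols), MISSING, dtype=np.int8)
        for k, v in enumerate(raw):
            if pd.isna(v) or str(v).upper() in ("NA", "."):
                continue
            try:
                code = int(v)
            except (TypeError, ValueError):
                raise InputFormatError(
                    f"{path}: line {r + 2}, column '{progeny_cols[k]}': "
                    f"invalid genotype code {v!r}"
                ) from None
            if code not in (0, 1, 2):
                raise InputFormatError(
                    f"{path}: line {r + 2}, column '{progeny_cols[k]}': "
                    f"genotype code {code} outside 0/1/2"
                )
            codes[k] = code
        if "seg_type" in df.columns and not pd.isna(row["seg_type"]):
            try:
                seg = SegregationType(str(row["seg_type"]).lower())
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {r + 2}, field 'seg_type': unknown value {row['seg_type']!r}"
                ) from None
        else:
            seg = _infer_seg_type(codes, str(row["snp_id"]), path)
        try:
            pos = int(row["pos"])
        except (TypeError, ValueError):
            raise InputFormatError(
                f"{path}: line {r + 2}, field 'pos': invalid position {row['pos']!r}"
            ) from None
        snps.append(
            SnpRecord(
                snp_id=str(row["snp_id"]),
                chromosome=str(row["chrom"]),
                position=pos,
                seg_type=seg,
                genotypes=codes,
                progeny_ids=list(progeny_cols),
            )
        )
    return snps


def read_genotypes_vcf(
    path: str | Path,
    parent1: str | None = None,
    parent2: str | None = None,
) -> list[SnpRecord]:
    """Read genotypes from a VCF; progeny are the non-parent samples.

    With both parent sample names given, segregation type comes from the
    parental genotypes (non-segregating sites are skipped with a log
    message); otherwise it is inferred from the progeny genotype classes.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    parent_names = [p for p in (parent1, parent2) if p is not None]
    for p in parent_names:
        if p not in samples:
            raise InputFormatError(f"{path}: parent sample '{p}' not present in VCF header")
    progeny = [s for s in samples if s not in parent_names]
    prog_idx = [samples.index(s) for s in progeny]
    par_idx = [samples.index(p) for p in parent_names]

    snps = []
    for var in vcf:
        gts = var.gt_types  # 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        codes = np.full(len(progeny), MISSING, dtype=np.int8)
        mapping = {0: 0, 1: 1, 3: 2}
        for k, i in enumerate(prog_idx):
            codes[k] = mapping.get(int(gts[i]), MISSING)
        chrom = str(var.CHROM).removeprefix("chr")
        snp_id = f"{chrom}/{var.POS}"
        if len(par_idx) == 2:
            p1, p2 = (mapping.get(int(gts[i]), MISSING) for i in par_idx)
            if MISSING in (p1, p2):
                logger.info("%s skipped: missing parental genotype", snp_id)
                continue
            if p1 != 1 and p2 != 1:
                logger.info("%s skipped: both parents homozygous (non-segregating)", snp_id)
                continue
            seg = classify_segregation(p1, p2)
        else:
            seg = _infer_seg_type(codes, snp_id, path)
        snps.append(SnpRecord(snp_id, chrom, int(var.POS), seg, codes, list(progeny)))
    return snps


def read_genotypes(
    path: str | Path, parent1: str | None = None, parent2: str | None = None
) -> list[SnpRecord]:
    """Dispatch on extension: .vcf/.vcf.gz/.bcf to VCF, anything else TSV."""
    suffixes = [s.lower() for s in Path(path).suffixes]
    if ".vcf" in suffixes or ".bcf" in suffixes:
        return read_genotypes_vcf(path, parent1, parent2)
    return read_genotypes_tsv(path)


def write_genotypes_tsv(snps: list[SnpRecord], path: str | Path) -> None:
    """Write the SNP-by-progeny matrix this module's TSV reader consumes."""
    if not snps:
        raise ValueError("no SNPs to write")
    ids = snps[0].progeny_ids or [f"P{i + 1:04d}" for i in range(snps[0].genotypes.size)]
    rows = []
    for snp in snps:
        row = {
            "snp_id": snp.snp_id,
            "chrom": snp.chromosome,
            "pos": snp.position,
            "seg_type": snp.seg_type.value,
        }
        for pid, code in zip(ids, snp.genotypes):
            row[pid] = "NA" if code == MISSING else int(code)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path) -> list[LongitudinalTraitPair]:
    """Read long-format phenotypes into per-progeny trait pairs.

    Ages must form one common grid across progeny (the complete-case
    AR(1) likelihood requires it); progeny missing either trait at any
    common age are rejected here with a named error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("progeny_id", "trait", "age", "value"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column '{col}'")
    df["trait"] = df["trait"].astype(str).str.lower()
    known = {"height", "diameter", "h0"}
    bad = set(df["trait"]) - known
    if bad:
        raise InputFormatError(f"{path}: unknown trait value(s) {sorted(bad)!r}")

    h0_by_progeny: dict[str, float] = {}
    if "h0" in df.columns:
        for pid, sub in df.groupby("progeny_id"):
            vals = sub["h0"].dropna().unique()
            if len(vals) > 1:
                raise InputFormatError(f"{path}: progeny {pid}: conflicting h0 values {vals!r}")
            if len(vals) == 1:
                h0_by_progeny[str(pid)] = float(vals[0])
    for pid, sub in df[df["trait"] == "h0"].groupby("progeny_id"):
        vals = sub["value"].unique()
        if len(vals) > 1:
            raise InputFormatError(f"{path}: progeny {pid}: conflicting h0 rows {vals!r}")
        h0_by_progeny[str(pid)] = float(vals[0])
    if not h0_by_progeny:
        logger.info("%s: no establishment heights supplied; defaulting h0 to 0", path)

    core = df[df["trait"].isin(("height", "diameter"))]
    pairs = []
    n_nonmonotone = 0
    for pid, sub in core.groupby("progeny_id", sort=True):
        wide = sub.pivot_table(index="age", columns="trait", values="value")
        if "height" not in wide.columns or "diameter" not in wide.columns:
            raise InputFormatError(f"{path}: progeny {pid}: needs both height and diameter series")
        if wide[["height", "diameter"]].isna().any().any():
            missing_ages = wide.index[wide[["height", "diameter"]].isna().any(axis=1)].tolist()
            raise InputFormatError(
                f"{path}: progeny {pid}: missing trait value at age(s) {missing_ages!r}"
            )
        ages = wide.index.to_numpy(dtype=float)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", MonotonicityWarning)
            pairs.append(
                LongitudinalTraitPair(
                    progeny_id=str(pid),
                    ages=ages,
                    heights=wide["height"].to_numpy(dtype=float),
                    diameters=wide["diameter"].to_numpy(dtype=float),
                    h0=Establishment(h0_by_progeny.get(str(pid), 0.0)),
                )
            )
        if any(issubclass(w.category, MonotonicityWarning) for w in caught):
            n_nonmonotone += 1
    if not pairs:
        raise InputFormatError(f"{path}: no phenotype records found")
    if n_nonmonotone:
        # one summary instead of a warning per progeny
        logger.warning(
            "%s: %d of %d progeny have non-monotone height or diameter series",
            path,
            n_nonmonotone,
            len(pairs),
        )
    return pairs


def write_phenotypes_csv(pairs: list[LongitudinalTraitPair], path: str | Path) -> None:
    """Write the long-format CSV this module's reader consumes (with h0 rows)."""
    rows = []
    for p in pairs:
        rows.append({"progeny_id": p.progeny_id, "trait": "h0", "age": 0, "value": p.h0.h0})
        for t in range(p.T):
            rows.append(
                {"progeny_id": p.progeny_id, "trait": "height", "age": p.ages[t], "value": p.heights[t]}
            )
            rows.append(
                {
                    "progeny_id": p.progeny_id,
                    "trait": "diameter",
                    "age": p.ages[t],
                    "value": p.diameters[t],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results


def write_results_tsv(results: list[ScanResult], path: str | Path) -> None:
    df = results_table(results)
    df["p_value"] = df["p_value"].map(lambda p: f"{p:.6e}" if np.isfinite(p) else "NA")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manhattan_tsv(results: list[ScanResult], path: str | Path) -> None:
    manhattan_table(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
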