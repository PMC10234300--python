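"""Readers and writers: phased VCF, pedigree, genetic maps, reference tables."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import Haplotype, Individual, SiteList, Trio, TrioCohort
from .recomb import RecombinationMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_pedigree",
    "write_pedigree",
    "assemble_cohort",
    "read_trio_data",
    "read_recomb_map",
    "write_recomb_map",
    "read_reference_table",
    "write_reference_table",
]

REFTABLE_COLUMNS = ["model", "s", "h", "delta_homo", "delta_het"]


def read_phased_vcf(
    path: str | Path,
    polarization: Literal["alt_is_derived", "aa_tag"] = "alt_is_derived",
    strict: bool = False,
):
    """Read phased haplotypes at biallelic SNPs.

    Returns ``(sites, haplotypes, report)`` where ``haplotypes`` maps sample id
    to a pair of boolean derived-allele carrier vectors and ``report`` counts
    excluded sites by reason.  Under ``aa_tag`` polarization, sites whose
    INFO/AA equals the ALT allele have their genotypes flipped (ALT is then
    the ancestral allele); sites with AA matching neither allele are dropped.

    With ``strict=True`` any unphased or missing genotype raises instead of
    excluding the site.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []  # (2*n_samples,) bool per retained site
    report = {
        "retained": 0,
        "not_snp": 0,
        "multiallelic": 0,
        "unphased": 0,
        "missing_gt": 0,
        "bad_aa": 0,
        "flipped": 0,
    }

    for var in vcf:
        if len(var.ALT) != 1:
            report["multiallelic"] += 1
            continue
        if not var.is_snp:
            report["not_snp"] += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        bad = None
        for i, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], g[2]
            if a0 < 0 or a1 < 0:
                bad = "missing_gt"
                break
            if not phased:
                bad = "unphased"
                break
            alleles[2 * i] = a0
            alleles[2 * i + 1] = a1
        if bad is not None:
            if strict:
                raise ValueError(
                    f"{path}: {bad.replace('_', ' ')} at {var.CHROM}:{var.POS}"
                )
            report[bad] += 1
            logger.warning("excluding %s:%d (%s)", var.CHROM, var.POS, bad)
            continue

        derived = alleles == 1
        if polarization == "aa_tag":
            aa = var.INFO.get("AA")
            aa = aa.upper() if isinstance(aa, str) else None
            if aa == var.REF.upper():
                pass
            elif aa == var.ALT[0].upper():
                derived = ~derived
                report["flipped"] += 1
            else:
                report["bad_aa"] += 1
                continue

        chroms.append(var.CHROM)
        positions.append(var.POS - 1)  # VCF is 1-based
        columns.append(derived)
        report["retained"] += 1

    if report["retained"] == 0:
        raise ValueError(f"{path}: no phased biallelic SNPs retained")

    sites = SiteList(np.array(chroms, dtype=object), np.array(positions, dtype=np.int64))
    mat = np.stack(columns, axis=1)  # (2*n_samples, n_sites)
    haplotypes = {
        sid: (Haplotype(sites, mat[2 * i]), Haplotype(sites, mat[2 * i + 1]))
        for i, sid in enumerate(samples)
    }
    return sites, haplotypes, report


def write_phased_vcf(
    path: str | Path,
    sites: SiteList,
    haplotypes: dict[str, tuple[Haplotype, Haplotype]],
) -> None:
    """Write a minimal phased VCF (ALT is the derived allele, REF/ALT = A/T)."""
    samples = list(haplotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sites.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(len(sites)):
            gt = "\t".join(
                f"{int(haplotypes[s][0].carriers[j])}|{int(haplotypes[s][1].carriers[j])}"
                for s in samples
            )
            fh.write(
                f"{sites.chrom[j]}\t{sites.pos[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_pedigree(path: str | Path) -> list[dict]:
    """Read PED-like rows (FID IID FATHER MOTHER SEX); '0' marks missing.

    Returns one record per child that has both parents declared; children with
    a missing parent id are excluded with a warning.  Duplicated child ids are
    an error.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        dtype=str,
        names=["fid", "iid", "father", "mother", "sex"],
        usecols=range(5),
    )
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.father == "0" or row.mother == "0":
            if not (row.father == "0" and row.mother == "0"):
                logger.warning("pedigree: child %s has a missing parent; excluded", row.iid)
            continue
        if row.iid in seen:
            raise ValueError(f"{path}: duplicated child id {row.iid!r}")
        seen.add(row.iid)
        records.append(
            {"child": row.iid, "father": row.father, "mother": row.mother, "sex": row.sex}
        )
    return records


def write_pedigree(path: str | Path, cohort: TrioCohort) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(cohort.trios):
            fh.write(f"F{i}\t{t.mother.id}\t0\t0\t2\n")
            fh.write(f"F{i}\t{t.father.id}\t0\t0\t1\n")
            fh.write(f"F{i}\t{t.child.id}\t{t.father.id}\t{t.mother.id}\t0\n")


def assemble_cohort(
    sites: SiteList,
    haplotypes: dict[str, tuple[Haplotype, Haplotype]],
    ped_records: list[dict],
) -> TrioCohort:
    """Join genotype data with pedigree records into a TrioCohort.

    Children whose parents are absent from the genotype data are excluded
    with a warning.  ``n_children_of_couple`` is computed per couple.
    """
    kept = []
    for rec in ped_records:
        missing = [
            pid
            for pid in (rec["child"], rec["mother"], rec["father"])
            if pid not in haplotypes
        ]
        if missing:
            logger.warning(
                "trio for child %s excluded: %s absent from genotype data",
                rec["child"],
                ",".join(missing),
            )
            continue
        kept.append(rec)

    n_children: dict[tuple[str, str], int] = {}
    for rec in kept:
        key = (rec["mother"], rec["father"])
        n_children[key] = n_children.get(key, 0) + 1

    def individual(sample_id: str, sex: str) -> Individual:
        h1, h2 = haplotypes[sample_id]
        return Individual(sample_id, sex, h1, h2)

    trios = []
    for rec in kept:
        key = (rec["mother"], rec["father"])
        child_sex = "female" if rec.get("sex") == "2" else "male"
        trios.append(
            Trio(
                mother=individual(rec["mother"], "female"),
                father=individual(rec["father"], "male"),
                child=individual(rec["child"], child_sex),
                n_children_of_couple=n_children[key],
            )
        )
    return TrioCohort(trios, sites)


def read_trio_data(
    vcf_path: str | Path,
    ped_path: str | Path,
    polarization: Literal["alt_is_derived", "aa_tag"] = "alt_is_derived",
    strict: bool = False,
) -> TrioCohort:
    sites, haplotypes, _ = read_phased_vcf(vcf_path, polarization, strict)
    return assemble_cohort(sites, haplotypes, read_pedigree(ped_path))


def read_recomb_map(path: str | Path, sex: Literal["female", "male"]) -> RecombinationMap:
    """Read a 3-column TSV genetic map (chrom, pos_bp, cumulative_cM)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    # tolerate a single header line
    try:
        float(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    m = RecombinationMap(sex=sex)
    for chrom, grp in df.groupby(0, sort=False):
        m.add_chromosome(
            str(chrom),
            grp[1].astype(np.float64).to_numpy(),
            grp[2].astype(np.float64).to_numpy(),
        )
    return m


def write_recomb_map(path: str | Path, recmap: RecombinationMap) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcM\n")
        for chrom, (pos_bp, cum_cm) in recmap.chrom_maps.items():
            for p, c in zip(pos_bp, cum_cm):
                fh.write(f"{chrom}\t{p:.10g}\t{c:.12g}\n")


def write_reference_table(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in REFTABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    table.to_csv(path, index=False, columns=REFTABLE_COLUMNS, float_format="%.12g")


def read_reference_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            dtype={
                "model": str,
                "s": np.float64,
                "h": np.float64,
                "delta_homo": np.float64,
                "delta_het": np.float64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(_locate_bad_row(path, exc)) from exc
    missing = [c for c in REFTABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[REFTABLE_COLUMNS]


def _locate_bad_row(path: str | Path, exc: Exception) -> str:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            fields = line.rstrip("\n").split(",")
            if len(fields) != len(REFTABLE_COLUMNS):
                return f"{path}: malformed row at line {lineno}"
            for val in fields[1:]:
                try:
                    float(val)
                except ValueError:
                    return f"{path}: malformed row at line {lineno}"
    return f"{path}: malformed reference table ({exc})"
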