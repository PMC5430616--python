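"""Reading and writing genotype matrices: TSV dialect, PLINK bed/bim/fam, VCF.

All formats carry diploid A1-allele dosages.  The TSV dialect is a header row
``sample_id<TAB>snp1<TAB>...`` with 0/1/2/NA cells and a SNP-map sidecar
``<stem>.map.tsv`` with columns ``id chrom pos a1 a2 [cm]``.  PLINK bed is the
v1.00 SNP-major binary layout; in bed coding 0b00 is homozygous A1 (dosage 2),
0b10 heterozygous, 0b11 homozygous A2 and 0b01 missing.  VCF reading is done
through cyvcf2 (GT field only) with A1 taken as the REF allele; multi-allelic
or non-SNP records are skipped with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SnpRecord

__all__ = ["read_genotypes", "write_genotypes"]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# bed 2-bit code -> dosage of A1
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".bed", ".bim", ".fam"} or suffix == "":
        return "plink-bed"
    if suffix == ".vcf":
        return "vcf"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise ValueError(f"cannot infer genotype format from {path!r}")


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``plink-bed``, ``vcf`` or ``tsv``.

    For PLINK, ``path`` may be the ``.bed`` file or the fileset prefix.
    """
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _read_tsv(Path(path))
    if fmt == "vcf":
        return _read_vcf(Path(path))
    if fmt == "plink-bed":
        return _read_plink(Path(path))
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        _write_tsv(gm, Path(path))
    elif fmt == "vcf":
        _write_vcf(gm, Path(path))
    elif fmt == "plink-bed":
        _write_plink(gm, Path(path))
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


# --------------------------------------------------------------------- TSV


def _map_path(path: Path) -> Path:
    return path.with_suffix(".map.tsv")


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    if table.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    snp_ids = list(table.columns[1:])
    dosage = table[snp_ids].to_numpy(dtype=float)
    bad = dosage[~np.isnan(dosage)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        row = int(np.argwhere(~np.isnan(dosage) & ~np.isin(dosage, (0.0, 1.0, 2.0)))[0][0])
        raise ValueError(f"{path}: invalid dosage in data row {row + 1}")

    map_file = _map_path(path)
    snp_map = pd.read_csv(map_file, sep="\t", dtype={"id": str, "chrom": str})
    required = {"id", "chrom", "pos", "a1", "a2"}
    if not required.issubset(snp_map.columns):
        raise ValueError(f"{map_file}: SNP map needs columns {sorted(required)}")
    snp_map = snp_map.set_index("id")
    try:
        snp_map = snp_map.loc[snp_ids]
    except KeyError as exc:
        raise ValueError(f"{map_file}: SNP map is missing an id from {path}: {exc}") from None
    snps = [
        SnpRecord(
            id=sid,
            chromosome=str(row["chrom"]),
            position_bp=int(row["pos"]),
            allele_a1=str(row["a1"]),
            allele_a2=str(row["a2"]),
            genetic_pos_cm=float(row["cm"]) if "cm" in snp_map.columns and pd.notna(row.get("cm")) else None,
        )
        for sid, row in snp_map.iterrows()
    ]
    return GenotypeMatrix(list(table["sample_id"].astype(str)), snps, dosage)


def _write_tsv(gm: GenotypeMatrix, path: Path) -> None:
    table = pd.DataFrame(gm.dosage, columns=gm.snp_ids)
    table.insert(0, "sample_id", gm.samples)
    with np.errstate(invalid="ignore"):
        for col in gm.snp_ids:
            table[col] = table[col].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    table.to_csv(path, sep="\t", index=False)
    snp_map = pd.DataFrame(
        {
            "id": gm.snp_ids,
            "chrom": [s.chromosome for s in gm.snps],
            "pos": [s.position_bp for s in gm.snps],
            "a1": [s.allele_a1 for s in gm.snps],
            "a2": [s.allele_a2 for s in gm.snps],
            "cm": [s.genetic_pos_cm if s.genetic_pos_cm is not None else "" for s in gm.snps],
        }
    )
    snp_map.to_csv(_map_path(path), sep="\t", index=False)


# --------------------------------------------------------------------- PLINK


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in {".bed", ".bim", ".fam"} else path


def _read_plink(path: Path) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    samples = list(fam["iid"])
    snps = [
        SnpRecord(
            id=row.id,
            chromosome=row.chrom,
            position_bp=int(row.pos),
            allele_a1=row.a1,
            allele_a2=row.a2,
            genetic_pos_cm=float(row.cm) if float(row.cm) != 0.0 else None,
        )
        for row in bim.itertuples()
    ]
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed v1.00 file")
    n, m = len(samples), len(snps)
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed: expected {bytes_per_snp * m} data bytes for "
            f"{n} samples x {m} SNPs, found {body.size}"
        )
    codes = body.reshape(m, bytes_per_snp)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts) & 0b11  # m x bytes x 4
    dosage = _BED_DECODE[expanded.reshape(m, -1)[:, :n]].T
    return GenotypeMatrix(samples, snps, dosage)


def _write_plink(gm: GenotypeMatrix, path: Path) -> None:
    prefix = _plink_prefix(path)
    bim = pd.DataFrame(
        {
            "chrom": [s.chromosome for s in gm.snps],
            "id": gm.snp_ids,
            "cm": [s.genetic_pos_cm or 0.0 for s in gm.snps],
            "pos": [s.position_bp for s in gm.snps],
            "a1": [s.allele_a1 for s in gm.snps],
            "a2": [s.allele_a2 for s in gm.snps],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": gm.samples,
            "iid": gm.samples,
            "pat": "0",
            "mat": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = gm.n_samples, gm.n_snps
    d = gm.dosage.T  # SNP-major
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    quads = code.reshape(m, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (quads << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# --------------------------------------------------------------------- VCF


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path), gts012=True)
    except Exception as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(reader.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    for variant in reader:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            warnings.warn(
                f"{path}: skipping multi-allelic or non-SNP record "
                f"{variant.ID or f'{variant.CHROM}:{variant.POS}'}"
            )
            continue
        snps.append(
            SnpRecord(
                id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                chromosome=str(variant.CHROM),
                position_bp=int(variant.POS),
                allele_a1=variant.REF,
                allele_a2=variant.ALT[0],
            )
        )
        # gts012: 0/1/2 alternate-allele count, 3 missing; A1 = REF dosage
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(2.0 - gt)
    dosage = np.column_stack(rows) if rows else np.zeros((len(samples), 0))
    return GenotypeMatrix(samples, snps, dosage)


_VCF_GT = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    chroms = list(dict.fromkeys(s.chromosome for s in gm.snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, snp in enumerate(gm.snps):
            gts = [
                "./." if np.isnan(v) else _VCF_GT[v] for v in gm.dosage[:, j]
            ]
            fh.write(
                f"{snp.chromosome}\t{snp.position_bp}\t{snp.id}\t"
                f"{snp.allele_a1}\t{snp.allele_a2}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
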