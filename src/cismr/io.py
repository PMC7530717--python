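"""File formats and run configuration.

Readers and writers for the formats the toolkit exchanges with standard
genetics software: PLINK 1 bed/bim/fam (v1.00, SNP-major), GT-only VCF 4.2,
GCTA ``.ma`` summary statistics (``SNP A1 A2 freq b se p N``), and phenotype
TSVs.  Dosages follow the package-wide convention of counting the A1 (effect)
allele; allele flips happen only during harmonization, never at read time.

Every reader keeps per-stage counters (variants read / skipped / imputed) in
the module logger so upstream filters stay auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import MA_COLUMNS, SummaryStats
from .genotype_sim import GenotypeMatrix

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_sumstats",
    "write_sumstats",
    "write_phenotypes",
    "read_phenotypes",
    "write_panel_metadata",
    "write_architecture",
    "read_architecture",
]

logger = logging.getLogger("cismr.io")

_BED_MAGIC = b"\x6c\x1b\x01"
# two-bit PLINK codes -> A1-allele dosage (01 = missing)
_BED_DECODE = {0b00: 2, 0b01: -1, 0b10: 1, 0b11: 0}
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


@dataclass
class RunConfig:
    """Thresholds, sizes and seeds for one analysis run; JSON round-trips."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.1
    cojo_collinearity_r2: float = 0.9
    tag_r2_lower: float = 0.1
    tag_r2_upper: float = 0.99
    tag_prune_r2: float = 0.95
    ridge_lambda: float | None = None
    cohort_sizes: tuple[int, int, int] = (15_000, 5_000, 5_000)
    n_variants: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = ("mr_link", "ivw")
    paths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["cohort_sizes"] = tuple(raw["cohort_sizes"])
        raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


# ---------------------------------------------------------------- PLINK bed


def write_genotypes(G: GenotypeMatrix, prefix: str | Path, fmt: str = "plink-bed") -> None:
    """Write a cohort as PLINK bed/bim/fam or a GT-only VCF."""
    if fmt == "plink-bed":
        _write_bed(G, Path(prefix))
    elif fmt == "vcf":
        _write_vcf(G, Path(str(prefix) + ".vcf"))
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(path: str | Path, fmt: str = "plink-bed") -> GenotypeMatrix:
    """Read genotypes; missing calls are imputed to the per-variant mean.

    ``path`` is the file-set prefix for PLINK and the .vcf path for VCF.
    """
    if fmt == "plink-bed":
        return _read_bed(Path(path))
    if fmt == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown genotype format {fmt!r}")


def _write_bed(G: GenotypeMatrix, prefix: Path) -> None:
    n, m = G.n_individuals, G.n_variants
    bim = pd.DataFrame(
        {
            "chrom": 1,
            "id": G.variant_ids,
            "cm": 0,
            "pos": G.positions,
            "a1": G.a1,
            "a2": G.a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    dosT = G.dosages.T
    for dos, code in _BED_ENCODE.items():
        codes[dosT == dos] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for offset in range(4):
        cols = np.arange(offset, n, 4)
        packed[:, : len(cols)] |= codes[:, cols] << (2 * offset)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bed = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)

    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{bed}: not a SNP-major PLINK 1 bed file (bad magic bytes)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise ValueError(
            f"{bed}: truncated or inconsistent with bim/fam "
            f"(expected {m * n_bytes} data bytes, found {body.size})"
        )
    body = body.reshape(m, n_bytes)
    dosages = np.empty((m, n), dtype=np.float64)
    for offset in range(4):
        cols = np.arange(offset, n, 4)
        twobit = (body[:, : len(cols)] >> (2 * offset)) & 0b11
        decode = np.array([_BED_DECODE[c] for c in range(4)], dtype=np.int8)
        dosages[:, cols] = decode[twobit]

    n_missing = int((dosages < 0).sum())
    if n_missing:
        logger.info("imputing %d missing genotype calls to per-variant means", n_missing)
        for j in range(m):
            row = dosages[j]
            miss = row < 0
            if miss.any():
                row[miss] = row[~miss].mean() if (~miss).any() else 0.0
    dosT = dosages.T
    if not n_missing:
        dosT = dosT.astype(np.int8)
    return GenotypeMatrix(
        dosages=dosT,
        variant_ids=bim["id"].to_numpy(dtype=object),
        positions=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(dtype=object),
        a2=bim["a2"].to_numpy(dtype=object),
    )


# --------------------------------------------------------------------- VCF


def _write_vcf(G: GenotypeMatrix, path: Path, contig: str = "1") -> None:
    n = G.n_individuals
    samples = "\t".join(f"I{i}" for i in range(n))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(G.n_variants):
            # ALT is the A1/effect allele so dosage = ALT allele count
            gts = "\t".join(gt_of[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{contig}\t{G.positions[j]}\t{G.variant_ids[j]}\t"
                f"{G.a2[j]}\t{G.a1[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    ids, pos, a1, a2, rows = [], [], [], [], []
    n_skipped = 0
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.rstrip("\n").split("\t")
                continue
            if header is None:
                raise ValueError(f"{path}: missing #CHROM header line")
            fields = line.rstrip("\n").split("\t")
            alt = fields[4]
            if "," in alt:
                n_skipped += 1
                continue
            gt_idx = fields[8].split(":").index("GT")
            dos = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = [a for a in gt.split("/") if a != "."]
                dos.append(sum(int(a) for a in alleles) if alleles else -1)
            rows.append(dos)
            ids.append(fields[2])
            pos.append(int(fields[1]))
            a2.append(fields[3])
            a1.append(alt)
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped)
    dosages = np.array(rows, dtype=np.float64).T
    miss = dosages < 0
    if miss.any():
        logger.info("imputing %d missing VCF genotypes to per-variant means", int(miss.sum()))
        for j in range(dosages.shape[1]):
            col = dosages[:, j]
            bad = col < 0
            if bad.any():
                col[bad] = col[~bad].mean() if (~bad).any() else 0.0
    else:
        dosages = dosages.astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array(ids, dtype=object),
        positions=np.array(pos),
        a1=np.array(a1, dtype=object),
        a2=np.array(a2, dtype=object),
    )


# ------------------------------------------------------------- summary stats


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write records in the GCTA ``.ma`` dialect (tab-separated, header)."""
    stats.table[MA_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str | Path, dialect: str = "ma") -> SummaryStats:
    """Read a ``.ma``-style TSV; extra columns are tolerated and ignored.

    Rows with non-positive SE or p outside (0, 1] are rejected with a logged
    count rather than silently kept.
    """
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = df[MA_COLUMNS].copy()
    ok = (
        np.isfinite(df["se"]) & (df["se"] > 0)
        & np.isfinite(df["p"]) & (df["p"] > 0) & (df["p"] <= 1)
        & np.isfinite(df["b"]) & (df["N"] >= 2)
    )
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("dropped %d malformed summary-statistic rows", n_drop)
    df = df[ok].reset_index(drop=True)
    return SummaryStats(table=df.assign(valid=True))


# ---------------------------------------------------------------- phenotypes


def write_phenotypes(path: str | Path, **columns: np.ndarray) -> None:
    """Write per-individual phenotype columns as a TSV with individual ids."""
    lengths = {len(v) for v in columns.values()}
    if len(lengths) != 1:
        raise ValueError("phenotype columns must have equal length")
    n = lengths.pop()
    df = pd.DataFrame({"individual_id": [f"I{i}" for i in range(n)], **columns})
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_panel_metadata(panel, path: str | Path) -> None:
    """Write per-variant panel metadata (id, position, allele-1 frequency)."""
    pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "position": panel.positions,
            "freq": panel.frequencies(),
        }
    ).to_csv(path, sep="\t", index=False)


def write_architecture(arch, path: str | Path) -> None:
    """Serialize a causal architecture (indices, effects, mode) to JSON."""
    payload = {
        "mode": arch.mode,
        "s_E": arch.s_E.tolist(),
        "s_U": arch.s_U.tolist(),
        "beta_E": arch.beta_E[arch.s_E].tolist(),
        "beta_U": arch.beta_U[arch.s_U].tolist(),
        "n_variants": len(arch.beta_E),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_architecture(path: str | Path):
    from .phenotype_sim import CausalArchitecture

    raw = json.loads(Path(path).read_text())
    m = raw["n_variants"]
    beta_E = np.zeros(m)
    beta_U = np.zeros(m)
    s_E = np.array(raw["s_E"], dtype=np.int64)
    s_U = np.array(raw["s_U"], dtype=np.int64)
    beta_E[s_E] = raw["beta_E"]
    beta_U[s_U] = raw["beta_U"]
    return CausalArchitecture(
        s_E=s_E, s_U=s_U, beta_E=beta_E, beta_U=beta_U, mode=raw["mode"]
    )
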