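"""Shared data model and readers/writers for the formats the pipeline touches.

Genotypes travel as a :class:`GenotypePanel`: an N x M matrix of allele-1
dosage counts (0/1/2, with a dedicated missing sentinel) plus an ordered SNP
map.  Positions are 1-based and annotation intervals are inclusive on both
ends, matching the PLINK BIM convention; all in-memory indexing is 0-based
offsets into map order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage call.  Never conflated with 0.
MISSING = np.int8(-9)

#: Chromosome labels treated as sex chromosomes and dropped on read by default.
SEX_CHROM_LABELS = frozenset({"X", "Y", "XY", "chrX", "chrY"})

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# PLINK 2-bit code -> dosage of allele 1 (A1).
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with its SNP map and sample ids."""

    samples: list
    snps: pd.DataFrame  # columns: snp, chrom, pos, a1, a2
    dosage: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("dosage values must be in {0,1,2,missing}")
        self.snps = self.snps.reset_index(drop=True)
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.snps["chrom"]))

    def snp_subset(self, idx: np.ndarray) -> "GenotypePanel":
        """New panel restricted to SNP map offsets ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(self.samples, self.snps.iloc[idx], self.dosage[:, idx])

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.snps["chrom"] == chrom).to_numpy())


@dataclass
class PhenotypeTable:
    """One record per sample: trait value, fixed-effect covariates, y_c."""

    data: pd.DataFrame
    id_col: str
    trait: str
    categorical: list
    numeric: list

    def __post_init__(self) -> None:
        ids = self.data[self.id_col]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.trait].to_numpy(dtype=float)

    @property
    def y_c(self) -> np.ndarray:
        if "y_c" not in self.data.columns:
            raise ValidationError("y_c has not been computed; run adjust_phenotype")
        return self.data["y_c"].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list:
        return list(self.data[self.id_col])


@dataclass
class GeneAnnotation:
    """Gene symbol intervals, 1-based inclusive on both ends."""

    table: pd.DataFrame  # columns: symbol, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] > t["end"]).any():
            raise ValidationError("annotation has start > end")
        if t.duplicated(["symbol", "chrom"]).any():
            raise ValidationError("duplicate (symbol, chrom) in annotation")
        self.table = t.reset_index(drop=True)

    @property
    def symbols(self) -> set:
        return set(self.table["symbol"])


@dataclass
class GeneLexicon:
    """Set of valid (uppercased) gene symbols with an optional alias map."""

    symbols: set
    aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = {s.upper() for s in self.symbols}
        if any(not s for s in self.symbols):
            raise ValidationError("empty gene symbol in lexicon")
        self.aliases = {a.upper(): c.upper() for a, c in self.aliases.items()}
        missing = set(self.aliases.values()) - self.symbols
        if missing:
            raise ValidationError(f"aliases resolve outside the lexicon: {missing}")

    def resolve(self, token: str):
        """Canonical symbol for ``token``, or None if not in the lexicon."""
        if token in self.symbols:
            return token
        return self.aliases.get(token)


@dataclass
class AbstractCorpus:
    """Document records: (id, title, abstract, trait tag)."""

    records: list  # list of dicts with keys id, title, abstract, trait

    def __post_init__(self) -> None:
        ids = [r["id"] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate document ids in corpus")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class SNPPartition:
    """Named index sets over a panel's SNP map order.

    The feature set ``tm`` and its complement ``exp`` always partition
    ``all``; an optional evenly-spaced control set ``em`` carries its own
    complement ``exp_em``.
    """

    def __init__(self, m: int, tm: np.ndarray | None = None,
                 em: np.ndarray | None = None):
        self.m = int(m)
        self._sets: dict[str, np.ndarray] = {"all": np.arange(self.m)}
        if tm is not None:
            tm = np.unique(np.asarray(tm, dtype=int))
            if tm.size and (tm[0] < 0 or tm[-1] >= self.m):
                raise ValidationError("tm indices outside SNP map")
            self._sets["tm"] = tm
            self._sets["exp"] = np.setdiff1d(self._sets["all"], tm)
        if em is not None:
            em = np.unique(np.asarray(em, dtype=int))
            if em.size and (em[0] < 0 or em[-1] >= self.m):
                raise ValidationError("em indices outside SNP map")
            self._sets["em"] = em
            self._sets["exp_em"] = np.setdiff1d(self._sets["all"], em)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list:
        return list(self._sets)

    def indices(self, name: str) -> np.ndarray:
        if name not in self._sets:
            raise ParameterError(f"unknown SNP set {name!r}; have {self.names}")
        return self._sets[name]

    def sizes(self) -> dict:
        return {k: v.size for k, v in self._sets.items()}


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

def read_plink(prefix, drop_sex_chroms: bool = True) -> GenotypePanel:
    """Read a PLINK .bed/.bim/.fam triple into a :class:`GenotypePanel`.

    Dosage is the count of allele 1 (BIM column 5).  SNP-major v1 BED files
    only.  With ``drop_sex_chroms`` (default), SNPs whose chromosome label is
    in :data:`SEX_CHROM_LABELS` are excluded at read time.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str, "fid": str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    if bim["snp"].duplicated().any():
        dup = bim.loc[bim["snp"].duplicated(), "snp"].iloc[0]
        raise FormatError(f"duplicate SNP id {dup!r} in BIM")
    if bim["pos"].isna().any() or (bim["pos"] <= 0).any():
        raise FormatError("BIM positions must be positive integers")

    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError("not a PLINK BED file (bad magic)")
    if raw[2] != _BED_SNP_MAJOR:
        raise FormatError("only SNP-major BED files are supported")
    bytes_per_snp = math.ceil(n / 4)
    if len(raw) - 3 != bytes_per_snp * m:
        raise FormatError(
            f"BED payload is {len(raw) - 3} bytes; expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # Unpack the four 2-bit genotype codes per byte (sample index runs LSB-first).
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosage = _BED_CODE_TO_DOSAGE[codes].T  # (n, m)

    samples = list(fam["iid"])
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]]
    panel = GenotypePanel(samples, snps, dosage)
    if drop_sex_chroms:
        keep = ~panel.snps["chrom"].isin(SEX_CHROM_LABELS)
        if not keep.all():
            logger.info("dropping %d SNPs on sex chromosomes", (~keep).sum())
            panel = panel.snp_subset(np.flatnonzero(keep.to_numpy()))
    return panel


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write ``panel`` as a SNP-major PLINK .bed/.bim/.fam triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame({
        "fid": panel.samples, "iid": panel.samples,
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = panel.snps.copy()
    bim.insert(2, "cm", 0)
    bim[["chrom", "snp", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = panel.n_samples, panel.n_snps
    bytes_per_snp = math.ceil(n / 4)
    code_of = np.zeros(256, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_BED_CODE.items():
        code_of[np.int8(dos).view(np.uint8)] = code
    codes = code_of[panel.dosage.T.view(np.uint8)]  # (m, n)
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded = padded.reshape(m, bytes_per_snp, 4)
    packed = (padded[:, :, 0] | (padded[:, :, 1] << 2)
              | (padded[:, :, 2] << 4) | (padded[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# Phenotypes, annotation, lexicon, corpus
# ---------------------------------------------------------------------------

def read_phenotypes(path, trait: str, id_col: str = "id",
                    categorical: list | None = None,
                    numeric: list | None = None) -> PhenotypeTable:
    """Read a phenotype + covariate CSV.

    Rows with missing trait values are flagged (column ``y_missing``), never
    dropped; rows with an empty covariate cell are flagged
    ``covariate_missing``.
    """
    categorical = list(categorical or [])
    numeric = list(numeric or [])
    df = pd.read_csv(path, dtype={id_col: str})
    for col in [id_col, trait, *categorical, *numeric]:
        if col not in df.columns:
            raise FormatError(f"column {col!r} missing from {path}")
    y = pd.to_numeric(df[trait], errors="coerce")
    bad = y.isna() & df[trait].notna()
    if bad.any():
        raise FormatError(f"non-numeric trait value {df.loc[bad, trait].iloc[0]!r}")
    df[trait] = y
    df["y_missing"] = y.isna()
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in categorical:
        df[col] = df[col].astype("string")
    cov = categorical + numeric
    df["covariate_missing"] = df[cov].isna().any(axis=1) if cov else False
    return PhenotypeTable(df, id_col, trait, categorical, numeric)


def read_annotation(path) -> GeneAnnotation:
    """Read gene intervals from a 4-column TSV: symbol, chrom, start, end."""
    t = pd.read_csv(path, sep="\t", header=None,
                    names=["symbol", "chrom", "start", "end"],
                    dtype={"symbol": str, "chrom": str})
    return GeneAnnotation(t)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", header=False, index=False)


def read_lexicon(path) -> GeneLexicon:
    """Read a lexicon TSV: ``symbol`` or ``alias<TAB>canonical`` per line."""
    symbols, aliases = set(), {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1 or not parts[1]:
            symbols.add(parts[0])
        else:
            aliases[parts[0]] = parts[1]
            symbols.add(parts[1])
    return GeneLexicon(symbols, aliases)


def write_lexicon(lex: GeneLexicon, path) -> None:
    lines = sorted(lex.symbols) + [f"{a}\t{c}" for a, c in sorted(lex.aliases.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_corpus(path) -> AbstractCorpus:
    """Read an abstract corpus from JSONL (keys: id, title, abstract, trait)."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        records.append({"id": rec["id"], "title": rec.get("title", ""),
                        "abstract": rec.get("abstract", ""),
                        "trait": rec.get("trait", "")})
    return AbstractCorpus(records)


def write_corpus(corpus: AbstractCorpus, path) -> None:
    with open(path, "w") as fh:
        for rec in corpus:
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# SNP extract lists (PLINK --extract convention)
# ---------------------------------------------------------------------------

def write_snp_extract(panel: GenotypePanel, partition: SNPPartition,
                      which: str, path) -> None:
    """Write the SNP ids of one partition set, one per line, in map order."""
    idx = partition.indices(which)
    if idx.size == 0:
        logger.warning("SNP set %r is empty; writing empty extract file", which)
    ids = panel.snps["snp"].iloc[idx]
    Path(path).write_text("".join(f"{s}\n" for s in ids))


def read_snp_extract(panel: GenotypePanel, path) -> np.ndarray:
    """Map an extract file back to 0-based SNP offsets in ``panel``."""
    wanted = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    lookup = {s: i for i, s in enumerate(panel.snps["snp"])}
    missing = [s for s in wanted if s not in lookup]
    if missing:
        raise ValidationError(f"SNP ids not in panel: {missing[:5]}")
    return np.array(sorted(lookup[s] for s in wanted), dtype=int)
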