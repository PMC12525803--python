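"""Central SNP dataset container and file I/O.

The in-memory currency of the package is :class:`SNPDataset`: an
``individuals x loci`` matrix of diploid genotype codes

* ``0`` — homozygous for the reference allele,
* ``1`` — heterozygous,
* ``2`` — homozygous for the alternate (SNP) allele,
* ``-1`` (:data:`MISSING`) — no call / null allele,

plus per-individual metadata (id, population) and per-locus metadata
(id, chromosome, 1-based position, alleles, optional DArT quality
passthroughs).

Supported formats
-----------------
* DArT "two-row" SNP reports (CSV): each codominant SNP occupies two
  consecutive rows — a reference-allele row and a SNP-allele row of
  presence/absence scores per sample.  Single-row (dominant SilicoDArT)
  records are skipped with a logged count.
* VCF 4.2, relaxed PHYLIP and STRUCTURE exports for downstream tools.

Positions are 1-based inclusive everywhere; DArT reports and VCF agree
on this convention and no strand flipping is performed (the DArT tag
defines the reported alleles).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the int8 genotype matrix.
MISSING: int = -1

#: IUPAC ambiguity code for an unordered pair of bases (heterozygotes).
IUPAC_AMBIGUITY = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class IndividualInfo:
    """One genotyped accession: sample id and its population/variety label."""

    id: str
    population: str

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"individual {self.id!r} has an empty population label")


@dataclass
class LocusInfo:
    """Per-locus metadata.

    ``id`` follows the DArT clone-tag convention (e.g. ``100062028-27-C/T``).
    ``chromosome``/``position`` may be ``None`` for unmapped tags.
    ``reproducibility`` and the two average read-depth fields are passed
    through from the report when present; they cannot be recomputed from
    genotype codes.
    """

    id: str
    chromosome: str | None = None
    position: int | None = None
    ref_allele: str = "A"
    alt_allele: str = "C"
    reproducibility: float | None = None
    avg_count_ref: float | None = None
    avg_count_snp: float | None = None

    def __post_init__(self) -> None:
        if self.position is not None and self.position < 1:
            raise ValueError(f"locus {self.id!r}: position must be >= 1 (1-based)")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.id!r}: ref and alt alleles are identical")

    @property
    def mapped(self) -> bool:
        return self.chromosome is not None and self.position is not None


@dataclass
class SNPDataset:
    """Genotype matrix plus aligned individual and locus metadata.

    ``genotypes`` is ``int8`` with rows = individuals, columns = loci and
    values in ``{0, 1, 2, MISSING}``.  ``provenance`` is a free-text log of
    transformations applied (filters, conversions, simulation parameters).
    """

    genotypes: np.ndarray
    individuals: list[IndividualInfo]
    loci: list[LocusInfo]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        n_ind, n_loc = self.genotypes.shape
        if n_ind != len(self.individuals):
            raise ValueError(
                f"genotype rows ({n_ind}) != individuals ({len(self.individuals)})"
            )
        if n_loc != len(self.loci):
            raise ValueError(f"genotype cols ({n_loc}) != loci ({len(self.loci)})")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype cells outside {{0,1,2,missing}}")
        ind_ids = [i.id for i in self.individuals]
        if len(set(ind_ids)) != len(ind_ids):
            raise ValueError("duplicate individual ids")
        loc_ids = [l.id for l in self.loci]
        if len(set(loc_ids)) != len(loc_ids):
            raise ValueError("duplicate locus ids")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``population``."""
        idx = np.array(
            [i for i, ind in enumerate(self.individuals) if ind.population == population],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"no individuals in population {population!r}")
        return idx

    def dosages(self) -> np.ndarray:
        """Genotypes as float alt-allele dosages with ``NaN`` for missing."""
        d = self.genotypes.astype(float)
        d[self.genotypes == MISSING] = np.nan
        return d

    def log(self, message: str) -> None:
        self.provenance.append(message)
        logger.info(message)

    def subset(
        self,
        individuals: np.ndarray | None = None,
        loci: np.ndarray | None = None,
    ) -> "SNPDataset":
        """Return a copy restricted to the given row/column index arrays or masks."""
        ind_idx = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc_idx = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if ind_idx.dtype == bool:
            ind_idx = np.flatnonzero(ind_idx)
        if loc_idx.dtype == bool:
            loc_idx = np.flatnonzero(loc_idx)
        return SNPDataset(
            genotypes=self.genotypes[np.ix_(ind_idx, loc_idx)].copy(),
            individuals=[self.individuals[i] for i in ind_idx],
            loci=[replace(self.loci[j]) for j in loc_idx],
            provenance=list(self.provenance),
        )


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column individual→population map (TSV or CSV, header optional)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"population map {path}: expected two columns")
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if first[0] in {"id", "sample", "individual", "genotype"} or first[1] in {
        "population", "pop", "variety", "cluster",
    }:
        df = df.iloc[1:]
    return {str(r[0]).strip(): str(r[1]).strip() for r in df.itertuples(index=False)}


def write_popmap(ds: SNPDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tpopulation\n")
        for ind in ds.individuals:
            fh.write(f"{ind.id}\t{ind.population}\n")


# ---------------------------------------------------------------------------
# DArT two-row report
# ---------------------------------------------------------------------------

_META_EXACT = {
    "alleleid", "cloneid", "chrom", "chromosome", "chrompos", "pos", "position",
    "snp", "snpposition", "repavg", "reproducibility", "avgcountref",
    "avgcountsnp", "callrate",
}
_META_PREFIX = ("oneratio", "pic", "freqhom", "freqhet", "avgcount", "chrom")

_SNP_RE = re.compile(r"(?:(\d+):)?([ACGT])>([ACGT])", re.IGNORECASE)
_ID_ALLELE_RE = re.compile(r"-(\d+)-([ACGT])/([ACGT])$", re.IGNORECASE)


def _is_metadata_column(name: str) -> bool:
    low = str(name).strip().lower().replace("_", "").replace(" ", "")
    return low in _META_EXACT or low.startswith(_META_PREFIX)


def _parse_score(value) -> int | None:
    """Presence score of one allele row: 1, 0 or None (no call)."""
    if value is None:
        return None
    s = str(value).strip()
    if s in {"", "-", "NA", "nan", "NaN"}:
        return None
    f = float(s)
    if f not in (0.0, 1.0):
        raise FormatError(f"allele-row score {value!r} is not 0/1/-")
    return int(f)


def _alleles_for(locus_id: str, snp_field: str | None) -> tuple[str, str]:
    """Ref/alt bases from the SNP column (``27:C>T``) or the AlleleID suffix."""
    if snp_field:
        m = _SNP_RE.search(str(snp_field))
        if m:
            return m.group(2).upper(), m.group(3).upper()
    m = _ID_ALLELE_RE.search(locus_id)
    if m:
        return m.group(2).upper(), m.group(3).upper()
    return "A", "C"  # last resort: codes still carry the information


def read_dart_tworow(
    path: str | Path,
    population_map: str | Path | dict[str, str],
    metadata_columns: list[str] | None = None,
) -> SNPDataset:
    """Read a DArT two-row SNP report plus a population map.

    Each codominant SNP is two consecutive rows sharing an AlleleID: the
    reference-allele row then the SNP-allele row of 0/1 presence scores per
    sample.  Presence patterns map to codes: (1,0)→0, (0,1)→2, (1,1)→1,
    (0,0) or any no-call→missing.  Records whose AlleleID appears only once
    are dominant SilicoDArT markers and are skipped (count logged).

    Metadata columns are auto-detected as the leading block of recognized
    DArT column names; every remaining column is a sample.  Pass
    ``metadata_columns`` to override the auto-detection.
    """
    popmap = population_map if isinstance(population_map, dict) else read_popmap(population_map)
    df = pd.read_csv(path, dtype=str)
    if metadata_columns is None:
        meta_cols: list[str] = []
        for col in df.columns:
            if _is_metadata_column(col):
                meta_cols.append(col)
            else:
                break
        if not meta_cols:
            raise FormatError(f"{path}: no recognizable metadata columns at left edge")
    else:
        meta_cols = list(metadata_columns)
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns detected")

    unknown = [s for s in sample_cols if s not in popmap]
    if unknown:
        raise FormatError(
            "samples absent from population map: " + ", ".join(map(str, unknown))
        )

    def _col(*names: str) -> str | None:
        lut = {str(c).strip().lower().replace("_", ""): c for c in meta_cols}
        for n in names:
            if n in lut:
                return lut[n]
        return None

    id_col = _col("alleleid", "cloneid") or meta_cols[0]
    chrom_col = _col("chrom", "chromosome")
    pos_col = _col("chrompos", "position", "pos")
    snp_col = _col("snp")
    rep_col = _col("repavg", "reproducibility")
    acr_col = _col("avgcountref")
    acs_col = _col("avgcountsnp")

    # consecutive-row grouping by AlleleID, preserving file order
    ids = df[id_col].astype(str).tolist()
    groups: list[tuple[str, list[int]]] = []
    for i, locus_id in enumerate(ids):
        if groups and groups[-1][0] == locus_id:
            groups[-1][1].append(i)
        else:
            groups.append((locus_id, [i]))
    counts = pd.Series([locus_id for locus_id, _ in groups]).value_counts()
    repeated = counts[counts > 1]
    if len(repeated):
        raise FormatError(
            "AlleleID appears in non-adjacent row blocks: "
            + ", ".join(repeated.index[:5])
        )

    loci: list[LocusInfo] = []
    codes: list[np.ndarray] = []
    n_silico = 0
    for locus_id, rows in groups:
        if len(rows) == 1:
            n_silico += 1
            continue
        if len(rows) != 2:
            raise FormatError(f"locus {locus_id!r}: expected 2 rows, found {len(rows)}")
        ref_row, snp_row = df.iloc[rows[0]], df.iloc[rows[1]]
        ref_allele, alt_allele = _alleles_for(
            locus_id, str(snp_row[snp_col]) if snp_col else None
        )

        def _opt_float(row, col):
            if col is None or pd.isna(row[col]) or str(row[col]).strip() == "":
                return None
            return float(row[col])

        chrom = None
        if chrom_col is not None and not pd.isna(ref_row[chrom_col]):
            chrom = str(ref_row[chrom_col]).strip() or None
        pos = None
        if pos_col is not None and not pd.isna(ref_row[pos_col]):
            s = str(ref_row[pos_col]).strip()
            pos = int(float(s)) if s else None
        loci.append(
            LocusInfo(
                id=locus_id,
                chromosome=chrom,
                position=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                reproducibility=_opt_float(ref_row, rep_col),
                avg_count_ref=_opt_float(ref_row, acr_col),
                avg_count_snp=_opt_float(snp_row, acs_col),
            )
        )
        col = np.full(len(sample_cols), MISSING, dtype=np.int8)
        for k, sample in enumerate(sample_cols):
            r = _parse_score(ref_row[sample])
            s = _parse_score(snp_row[sample])
            if r is None or s is None or (r == 0 and s == 0):
                continue
            col[k] = 1 if (r == 1 and s == 1) else (0 if r == 1 else 2)
        codes.append(col)

    if not loci:
        raise FormatError(f"{path}: no two-row SNP records found")
    genotypes = np.stack(codes, axis=1)
    individuals = [IndividualInfo(id=s, population=popmap[s]) for s in sample_cols]
    ds = SNPDataset(genotypes=genotypes, individuals=individuals, loci=loci)
    ds.log(
        f"read_dart_tworow: {len(loci)} SNP loci x {len(sample_cols)} samples "
        f"from {path} ({n_silico} single-row SilicoDArT records skipped)"
    )
    return ds


def write_dart_tworow(ds: SNPDataset, path: str | Path) -> None:
    """Write the two-row dialect this package reads (round-trip safe)."""
    meta_header = ["AlleleID", "Chrom", "ChromPos", "SNP", "RepAvg", "AvgCountRef", "AvgCountSnp"]
    rows = []
    for j, loc in enumerate(ds.loci):
        snp_field = f"{loc.position or 0}:{loc.ref_allele}>{loc.alt_allele}"
        g = ds.genotypes[:, j]
        ref_scores = np.where(g == MISSING, None, np.isin(g, (0, 1)).astype(int))
        snp_scores = np.where(g == MISSING, None, np.isin(g, (1, 2)).astype(int))

        def fmt(x):
            return "-" if x is None else str(int(x))

        common = [
            loc.id,
            loc.chromosome if loc.chromosome is not None else "",
            str(loc.position) if loc.position is not None else "",
            snp_field,
            "" if loc.reproducibility is None else repr(loc.reproducibility),
        ]
        rows.append(
            common
            + ["" if loc.avg_count_ref is None else repr(loc.avg_count_ref), ""]
            + [fmt(x) for x in ref_scores]
        )
        rows.append(
            common
            + ["", "" if loc.avg_count_snp is None else repr(loc.avg_count_snp)]
            + [fmt(x) for x in snp_scores]
        )
    header = meta_header + [ind.id for ind in ds.individuals]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# exporters
# ---------------------------------------------------------------------------

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: SNPDataset, path: str | Path) -> int:
    """Export mapped loci as VCF 4.2 (GT only). Returns the number written.

    Unmapped loci (no chromosome/position) are omitted with a logged count;
    locus order is otherwise preserved so that a read-back reproduces the
    genotype matrix column-for-column.
    """
    mapped = [j for j, loc in enumerate(ds.loci) if loc.mapped]
    n_skipped = ds.n_loci - len(mapped)
    chroms: dict[str, None] = {}
    for j in mapped:
        chroms.setdefault(str(ds.loci[j].chromosome), None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=beanpop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ind.id for ind in ds.individuals)
            + "\n"
        )
        for j in mapped:
            loc = ds.loci[j]
            gts = "\t".join(_VCF_GT[int(g)] for g in ds.genotypes[:, j])
            fh.write(
                f"{loc.chromosome}\t{loc.position}\t{loc.id}\t"
                f"{loc.ref_allele}\t{loc.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )
    ds.log(f"write_vcf: {len(mapped)} loci written to {path}, {n_skipped} unmapped skipped")
    return len(mapped)


def _phylip_char(code: int, ref: str, alt: str) -> str:
    if code == 0:
        return ref
    if code == 2:
        return alt
    if code == 1:
        return IUPAC_AMBIGUITY.get(frozenset((ref.upper(), alt.upper())), "N")
    return "N"


def write_phylip(ds: SNPDataset, path: str | Path) -> None:
    """Relaxed PHYLIP: one character per locus (IUPAC ambiguity for hets, N missing)."""
    names = []
    seen: dict[str, int] = {}
    for ind in ds.individuals:
        name = re.sub(r"\s+", "_", ind.id)
        if name in seen:
            seen[name] += 1
            disambiguated = f"{name}_{seen[name]}"
            logger.warning("write_phylip: duplicate name %r renamed %r", name, disambiguated)
            name = disambiguated
        else:
            seen[name] = 0
        names.append(name)
    with open(path, "w") as fh:
        fh.write(f" {ds.n_individuals} {ds.n_loci}\n")
        for i, name in enumerate(names):
            seq = "".join(
                _phylip_char(int(g), loc.ref_allele, loc.alt_allele)
                for g, loc in zip(ds.genotypes[i], ds.loci)
            )
            fh.write(f"{name}  {seq}\n")


#: STRUCTURE allele pair per genotype code (ref allele = 1, alt allele = 2).
_STRUCTURE_ALLELES = {0: (1, 1), 1: (1, 2), 2: (2, 2), MISSING: (-9, -9)}


def write_structure(ds: SNPDataset, path: str | Path) -> None:
    """STRUCTURE input: two rows per individual, one allele per row, -9 missing."""
    pop_index = {p: k + 1 for k, p in enumerate(ds.populations)}
    with open(path, "w") as fh:
        for i, ind in enumerate(ds.individuals):
            pairs = [_STRUCTURE_ALLELES[int(g)] for g in ds.genotypes[i]]
            for phase in (0, 1):
                alleles = "\t".join(str(p[phase]) for p in pairs)
                fh.write(f"{ind.id}\t{pop_index[ind.population]}\t{alleles}\n")
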