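"""DArT two-row parsing, exporters, and round-trip identity."""

import numpy as np
import pytest

from beanpop import (
    MISSING,
    SimulationConfig,
    read_dart_tworow,
    simulate_dataset,
    write_dart_tworow,
    write_phylip,
    write_popmap,
    write_structure,
    write_vcf,
)
from beanpop.dart_io import FormatError

from conftest import make_dataset

TWOROW_HEADER = "AlleleID,Chrom,ChromPos,SNP,RepAvg,AvgCountRef,AvgCountSnp,S1,S2,S3\n"
POPMAP = "id\tpopulation\nS1\tA\nS2\tA\nS3\tB\n"


def _write(tmp_path, csv_body, popmap=POPMAP):
    csv_path = tmp_path / "report.csv"
    csv_path.write_text(TWOROW_HEADER + csv_body)
    pop_path = tmp_path / "pops.tsv"
    pop_path.write_text(popmap)
    return csv_path, pop_path


def test_presence_patterns_map_to_codes(tmp_path):
    """(1,0)→hom ref, (0,1)→hom alt, (1,1)→het, (0,0) or '-'→missing."""
    body = (
        "100062028-27-C/T,1,100,27:C>T,1.0,10,,1,0,1\n"
        "100062028-27-C/T,1,100,27:C>T,1.0,,8,0,1,1\n"
        "tag2-5-A/G,2,200,5:A>G,1.0,,,0,1,-\n"
        "tag2-5-A/G,2,200,5:A>G,1.0,,,0,1,1\n"
    )
    ds = read_dart_tworow(*_write(tmp_path, body))
    np.testing.assert_array_equal(ds.genotypes[:, 0], [0, 2, 1])
    np.testing.assert_array_equal(ds.genotypes[:, 1], [MISSING, 1, MISSING])
    loc = ds.loci[0]
    assert (loc.ref_allele, loc.alt_allele) == ("C", "T")
    assert loc.chromosome == "1" and loc.position == 100
    assert ds.loci[0].avg_count_ref == 10 and ds.loci[0].avg_count_snp == 8


def test_silico_single_rows_are_skipped(tmp_path):
    body = (
        "silico1,1,50,,1.0,,,1,0,1\n"  # dominant marker: one row only
        "tag1-1-A/C,1,100,1:A>C,1.0,,,1,1,0\n"
        "tag1-1-A/C,1,100,1:A>C,1.0,,,0,1,0\n"
    )
    ds = read_dart_tworow(*_write(tmp_path, body))
    assert ds.n_loci == 1
    assert "1 single-row SilicoDArT" in ds.provenance[0]


def test_unpaired_rows_raise_naming_locus(tmp_path):
    body = "tag1-1-A/C,1,100,1:A>C,1.0,,,1,1,0\n" * 3
    with pytest.raises(FormatError, match="tag1-1-A/C"):
        read_dart_tworow(*_write(tmp_path, body))


def test_sample_missing_from_popmap_raises(tmp_path):
    body = (
        "tag1-1-A/C,1,100,1:A>C,1.0,,,1,1,0\n"
        "tag1-1-A/C,1,100,1:A>C,1.0,,,0,1,0\n"
    )
    with pytest.raises(FormatError, match="S3"):
        read_dart_tworow(*_write(tmp_path, body, popmap="id\tpopulation\nS1\tA\nS2\tA\n"))


def test_tworow_roundtrip_identity(tmp_path):
    ds = simulate_dataset(
        SimulationConfig(n_pops=2, n_ind=(3, 4), n_loci=25, seed=11, missing_rate=0.1)
    )
    write_dart_tworow(ds, tmp_path / "out.csv")
    write_popmap(ds, tmp_path / "pops.tsv")
    back = read_dart_tworow(tmp_path / "out.csv", tmp_path / "pops.tsv")
    np.testing.assert_array_equal(back.genotypes, ds.genotypes)
    assert [l.id for l in back.loci] == [l.id for l in ds.loci]
    assert [(l.chromosome, l.position) for l in back.loci] == [
        (l.chromosome, l.position) for l in ds.loci
    ]
    assert [(i.id, i.population) for i in back.individuals] == [
        (i.id, i.population) for i in ds.individuals
    ]


def test_vcf_roundtrip_via_cyvcf2(tmp_path):
    cyvcf2 = pytest.importorskip("cyvcf2")
    ds = simulate_dataset(
        SimulationConfig(n_pops=2, n_ind=(4, 4), n_loci=30, seed=7, missing_rate=0.1)
    )
    path = tmp_path / "panel.vcf"
    write_vcf(ds, path)
    vcf = cyvcf2.VCF(str(path))
    assert vcf.samples == [i.id for i in ds.individuals]
    codes = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types: HOM_REF/HET/UNKNOWN/HOM_ALT
    rebuilt = []
    ids = []
    for var in vcf:
        rebuilt.append([codes[t] for t in var.gt_types])
        ids.append(var.ID)
        assert var.POS >= 1
    np.testing.assert_array_equal(np.array(rebuilt).T, ds.genotypes)
    assert ids == [l.id for l in ds.loci]


def test_vcf_encoding_table(tmp_path):
    ds = make_dataset([[0, 1], [2, -1]], ["A", "B"])
    write_vcf(ds, tmp_path / "x.vcf")
    lines = [l for l in (tmp_path / "x.vcf").read_text().splitlines() if not l.startswith("#")]
    assert lines[0].split("\t")[9:] == ["0/0", "1/1"]
    assert lines[1].split("\t")[9:] == ["0/1", "./."]


def test_vcf_skips_unmapped_loci(tmp_path):
    ds = make_dataset([[0, 1], [2, 0]], ["A", "B"])
    ds.loci[1].chromosome = None
    ds.loci[1].position = None
    n = write_vcf(ds, tmp_path / "x.vcf")
    assert n == 1


def test_phylip_characters_and_header(tmp_path):
    # locus 0 is C/T: het → IUPAC Y; all-missing individual → all-N row
    ds = make_dataset([[1, 0], [-1, -1]], ["A", "B"])
    ds.loci[0].ref_allele, ds.loci[0].alt_allele = "C", "T"
    write_phylip(ds, tmp_path / "x.phy")
    lines = (tmp_path / "x.phy").read_text().splitlines()
    assert lines[0].split() == ["2", "2"]
    assert lines[1].split()[1][0] == "Y"
    assert lines[2].split()[1] == "NN"


def test_structure_encoding(tmp_path):
    ds = make_dataset([[0, 1, 2, -1]], ["A"])
    write_structure(ds, tmp_path / "x.str")
    rows = [l.split("\t") for l in (tmp_path / "x.str").read_text().splitlines()]
    assert len(rows) == 2  # two rows per individual
    assert [r[2:] for r in rows] == [["1", "1", "2", "-9"], ["1", "2", "2", "-9"]]
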