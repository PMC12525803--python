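"""End-to-end workflow: read/simulate → filter → analyses → exports.

`run_pipeline` executes the standard characterization of a DArTseq SNP
panel from a single :class:`RunConfig` (usually parsed from YAML):
locus metrics, call-rate/monomorphic filtering, diversity indexes, the
exact-HWE screen, pairwise allele sharing, LD (on a MAF-filtered copy),
AMOVA and PCA, plus VCF/PHYLIP/STRUCTURE exports.  Every stage writes a
TSV into the output directory and appends to a JSON run manifest, so a
rerun with the same config and seeds is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allele_sharing import sharing_matrix
from .dart_io import SNPDataset, read_dart_tworow, write_phylip, write_popmap, write_structure, write_vcf
from .diversity import diversity_report
from .filtering import FilterReport, filter_individuals, filter_loci, filter_maf, remove_monomorphic
from .hwe import hwe_screen
from .ld import ld_pairs, ld_summaries
from .locus_metrics import compute_locus_metrics, individual_call_rates, snp_density
from .structure_stats import amova, pca
from .synthetic_data import SimulationConfig, simulate_dataset

#: published assembly size of the reference genome, bp
DEFAULT_GENOME_SIZE_BP = 537_200_000

_FLOAT_FMT = "%.9g"


def per_snp_span(n_loci: int, genome_size_bp: float = DEFAULT_GENOME_SIZE_BP) -> float:
    """Mean genome span per retained SNP, in bp (genome size / locus count)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return genome_size_bp / n_loci


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML via `from_yaml`."""

    outdir: str = "beanpop_out"
    seed: int = 0
    dart: str | None = None
    popmap: str | None = None
    simulate: dict | None = None
    min_ind_call: float = 0.8
    min_locus_call: float = 0.95
    drop_monomorphic: bool = True
    ld_min_maf: float = 0.05
    ld_n_perm: int = 1000
    ld_max_pairs: int = 2_000_000
    amova_n_perm: int = 999
    pca_axes: int = 10
    density_bin_bp: int = 200_000
    genome_size_bp: float = DEFAULT_GENOME_SIZE_BP
    stages: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_enabled(self, name: str) -> bool:
        return self.stages.get(name, True)


def _load_input(cfg: RunConfig) -> SNPDataset:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        if "n_ind" in sim:
            sim["n_ind"] = tuple(sim["n_ind"])
        return simulate_dataset(SimulationConfig(**sim))
    if cfg.dart is None or cfg.popmap is None:
        raise ValueError("config needs either a `simulate` block or `dart` + `popmap` paths")
    return read_dart_tworow(cfg.dart, cfg.popmap)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "outputs": [],
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    def emit(name: str) -> Path:
        path = outdir / name
        manifest["outputs"].append(str(path))
        return path

    try:
        ds = _load_input(cfg)
        record("load", individuals=ds.n_individuals, loci=ds.n_loci)

        reports: list[FilterReport] = []
        ds, rep = filter_individuals(ds, cfg.min_ind_call)
        reports.append(rep)
        ds, rep = filter_loci(ds, cfg.min_locus_call)
        reports.append(rep)
        if cfg.drop_monomorphic:
            ds, rep = remove_monomorphic(ds)
            reports.append(rep)
        _write_tsv(
            pd.DataFrame([asdict(r) for r in reports]).set_index("stage"),
            emit("filter_report.tsv"),
        )
        record(
            "filter",
            order=[r.stage for r in reports],
            retained_individuals=ds.n_individuals,
            retained_loci=ds.n_loci,
            per_snp_span_bp=per_snp_span(ds.n_loci, cfg.genome_size_bp),
        )

        if cfg.stage_enabled("metrics"):
            _write_tsv(compute_locus_metrics(ds), emit("locus_metrics.tsv"), "locus")
            _write_tsv(
                individual_call_rates(ds).to_frame(), emit("individual_call_rates.tsv"), "id"
            )
            density = snp_density(ds, cfg.density_bin_bp)
            dens_rows = [
                {"chromosome": c, "bin": k, "start_bp": k * cfg.density_bin_bp + 1, "count": int(v)}
                for c, counts in density.items()
                for k, v in enumerate(counts)
            ]
            _write_tsv(pd.DataFrame(dens_rows).set_index("chromosome"), emit("snp_density.tsv"))
            record("metrics", loci=ds.n_loci)

        if cfg.stage_enabled("diversity"):
            _write_tsv(diversity_report(ds), emit("diversity.tsv"))
            record("diversity", populations=len(ds.populations))

        if cfg.stage_enabled("hwe"):
            hits = hwe_screen(ds)
            _write_tsv(
                pd.DataFrame([asdict_hwe(h) for h in hits]),
                emit("hwe_departures.tsv"),
            )
            record("hwe", significant=len(hits))

        if cfg.stage_enabled("sharing"):
            pair_rows = []
            for r in sharing_matrix(ds):
                row = {
                    "pop1": r.pop1, "pop2": r.pop2, "fixed": r.fixed,
                    "priv1": r.priv1, "priv2": r.priv2, "chao1": r.chao1,
                    "chao2": r.chao2, "totalpriv": r.totalpriv, "afd": r.afd,
                }
                pair_rows.append(row)
            _write_tsv(pd.DataFrame(pair_rows).set_index(["pop1", "pop2"]), emit("allele_sharing.tsv"))
            record("sharing", pairs=len(pair_rows))

        if cfg.stage_enabled("ld"):
            ld_ds, _ = filter_maf(ds, cfg.ld_min_maf)
            within = ld_pairs(
                ld_ds, "within", max_pairs=cfg.ld_max_pairs,
                n_perm=cfg.ld_n_perm, seed=cfg.seed,
            )
            between = ld_pairs(
                ld_ds, "between", max_pairs=min(cfg.ld_max_pairs, max(len(within), 100)),
                n_perm=cfg.ld_n_perm, seed=cfg.seed + 1,
            )
            pair_frame = pd.DataFrame(
                [
                    {
                        "locus_a": p.locus_a, "locus_b": p.locus_b,
                        "chromosome": p.chromosome_a if p.distance is not None else "",
                        "distance_bp": "" if p.distance is None else int(p.distance),
                        "r2": p.r2, "p_value": p.p_value, "n_used": p.n_used,
                    }
                    for p in within + between
                ]
            )
            _write_tsv(pair_frame.set_index("locus_a"), emit("ld_pairs.tsv"))
            summaries = ld_summaries(within + between)
            summ_frame = pd.DataFrame(
                [
                    {
                        "chromosome": s.chromosome, "n_pairs": s.n_pairs,
                        "mean_r2": s.mean_r2, "prop_significant": s.prop_significant,
                        "mean_r2_unlinked": s.mean_r2_unlinked,
                        "d_crossing_bp": s.d_crossing, "low_confidence": s.low_confidence,
                    }
                    for s in summaries
                ]
            )
            _write_tsv(summ_frame.set_index("chromosome"), emit("ld_summary.tsv"))
            decay_rows = [
                {"chromosome": s.chromosome, "distance_bp": d, "fitted_r2": r}
                for s in summaries
                if s.decay_distance is not None
                for d, r in zip(s.decay_distance, s.decay_r2)
            ]
            if decay_rows:
                _write_tsv(pd.DataFrame(decay_rows).set_index("chromosome"), emit("ld_decay.tsv"))
            record("ld", within_pairs=len(within), between_pairs=len(between))

        if cfg.stage_enabled("amova"):
            res = amova(ds, n_perm=cfg.amova_n_perm, seed=cfg.seed + 2)
            with open(emit("amova.json"), "w") as fh:
                json.dump(
                    {
                        "sigma2": res.sigma2, "percent": res.percent,
                        "df": res.df, "ss": res.ss,
                        "phi": {"phi_st": res.phi_st, "phi_is": res.phi_is, "phi_it": res.phi_it},
                        "p_values": res.p_values, "n_permutations": res.n_permutations,
                    },
                    fh, indent=2,
                )
            record("amova", phi_st=res.phi_st, p=res.p_values["among_populations"])

        if cfg.stage_enabled("pca"):
            res = pca(ds, n_axes=cfg.pca_axes)
            frame = res.scores.copy()
            _write_tsv(frame, emit("pca_scores.tsv"), "id")
            _write_tsv(
                pd.DataFrame(
                    {"axis": [f"PC{a + 1}" for a in range(len(res.explained_percent))],
                     "explained_percent": res.explained_percent}
                ).set_index("axis"),
                emit("pca_explained.tsv"),
            )
            record("pca", pc1_percent=float(res.explained_percent[0]))

        if cfg.stage_enabled("exports"):
            write_vcf(ds, emit("panel.vcf"))
            write_phylip(ds, emit("panel.phy"))
            write_structure(ds, emit("panel.str"))
            write_popmap(ds, emit("panel.popmap.tsv"))
            record("exports", formats=["vcf", "phylip", "structure"])

        manifest["provenance"] = ds.provenance
        manifest["status"] = "complete"
    except Exception as exc:  # halt but keep the partial manifest on disk
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def asdict_hwe(h) -> dict:
    return {
        "locus": h.locus, "population": h.population, "hom_1": h.n_hom1,
        "het": h.n_het, "hom_2": h.n_hom2, "n": h.n, "prob": h.p_value,
    }
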