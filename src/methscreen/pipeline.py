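"""End-to-end pipeline: estimate -> screen -> enrich -> associate.

A :class:`PipelineConfig` names either file inputs (probe table, CpG
map, ROIs, gene sets, subject phenotypes) or a ``simulate`` block, in
which case the synthetic generators produce the inputs first and write
them beside the outputs.  Reruns with the same config and seed are
bitwise-identical; the manifest records the seed, package version and
sha256 of every file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import associate_all
from .batman_lite import estimate_matrix
from .dmr import DMRThresholds, GroupDesign, call_dmrs
from .enrichment import call_dmrois, geneset_enrichment, rois_from_frame
from .io import (
    read_bed,
    read_gmt,
    read_probe_table,
    sha256_of,
    write_bed,
    write_gmt,
    write_methylation_matrix,
)
from .synthetic import (
    LinkFunction,
    SimulationConfig,
    array_rois,
    simulate_array_cohort,
    simulate_cpg_map,
    simulate_gene_sets,
    simulate_probe_signals,
    simulate_validation_cohort,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "default_config"]


@dataclass
class PipelineConfig:
    outdir: str = "methscreen_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    probes: str | None = None
    cpg_map: str | None = None
    rois: str | None = None
    gene_sets: str | None = None
    phenotypes: str | None = None
    groups: str | None = None  # TSV sample_id\tgroup for file-based runs
    link: dict | None = None  # link-function metadata for estimation
    noise_sd: float = 0.1  # observation SD for the grid posterior
    grid_step: float = 0.01
    thresholds: DMRThresholds = field(default_factory=DMRThresholds)
    tiers: tuple[str, ...] = ("sex", "sex+maternal")

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("probes", "cpg_map", "rois", "groups"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config needs either a simulate block or {name!r}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            if self.link is None:
                raise ValueError("file-based runs must supply link metadata")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    thr = raw.pop("thresholds", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "group_sizes" in sim:
            sim["group_sizes"] = tuple(sim["group_sizes"])
        if "cpg_corr_range" in sim:
            sim["cpg_corr_range"] = tuple(sim["cpg_corr_range"])
        cfg.simulate = SimulationConfig(**sim)
    if thr is not None:
        cfg.thresholds = DMRThresholds(**thr)
    if isinstance(cfg.tiers, list):
        cfg.tiers = tuple(cfg.tiers)
    return cfg


def default_config(outdir: str = "methscreen_out", seed: int = 0) -> PipelineConfig:
    """The bundled synthetic scenario: a 24-sample screen with one fully
    planted promoter ROI, gene sets, and a 175-subject validation cohort."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        simulate=SimulationConfig(
            n_regions=600,
            n_true_dmrs=12,
            cluster_dmrs=True,
            windows_per_roi=20,
            seed=seed,
        ),
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written as JSON).

    Stages: (synthetic input generation,) methylation estimation, DMR
    screen, ROI enrichment/DMROI calling, gene-set enrichment (skipped
    with a warning when no gene sets are available) and, when subject
    phenotypes exist, CpG-outcome association.  Any stage failure
    raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            cohort = simulate_array_cohort(sim)
            cpg_map = simulate_cpg_map(cohort)
            probes, link = simulate_probe_signals(cohort, cpg_map)
            rois_df = array_rois(cohort)
            planted = sorted(
                rois_df["gene_id"][
                    rois_df.index.isin(
                        assigned_rois_of_planted(cohort, rois_df)
                    )
                ]
            )
            gene_sets = simulate_gene_sets(rois_df, true_genes=planted, seed=sim.seed)
            validation = simulate_validation_cohort(sim)
            subjects = validation.to_frame()
            groups = cohort.group_labels
            sample_ids = cohort.sample_ids

            indir = outdir / "inputs"
            indir.mkdir(exist_ok=True)
            _write_tsv(probes, indir / "probes.tsv")
            write_bed(cpg_map, indir / "cpg_map.bed")
            _write_tsv(rois_df, indir / "rois.tsv")
            write_gmt(gene_sets, indir / "gene_sets.gmt")
            _write_tsv(subjects, indir / "subjects.tsv")
            groups.rename("group").to_frame().reset_index(names="sample_id").to_csv(
                indir / "groups.tsv", sep="\t", index=False
            )
            (indir / "metadata.json").write_text(
                json.dumps(
                    {"seed": sim.seed, "link": link.to_dict(),
                     "truth": {"n_true_dmrs": int(cohort.true_dmr_mask.sum()),
                               "planted_genes": planted}},
                    indent=2, sort_keys=True,
                )
                + "\n"
            )
            for f in indir.iterdir():
                inputs[f.name] = sha256_of(f)
            noise_sd = sim.probe_noise_sd if sim.probe_noise_sd > 0 else config.noise_sd
        else:
            config.validate()
            probes = read_probe_table(config.probes)
            cpg_map = read_bed(config.cpg_map)
            if "coupled_mass" not in probes.columns:
                from .batman_lite import compute_coupling

                pos_by_chrom = {
                    c: g["start"].to_numpy() for c, g in cpg_map.groupby("chrom")
                }
                probes["coupled_mass"] = [
                    compute_coupling((r.start, r.end),
                                     pos_by_chrom.get(r.chrom, []))[1]
                    for r in probes.itertuples(index=False)
                ]
            link = LinkFunction.from_dict(config.link)
            rois_df = pd.read_csv(config.rois, sep="\t")
            gtab = pd.read_csv(config.groups, sep="\t")
            groups = pd.Series(
                gtab["group"].to_numpy(), index=gtab["sample_id"], name="group"
            )
            sample_ids = list(groups.index)
            gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
            subjects = (
                pd.read_csv(config.phenotypes, sep="\t") if config.phenotypes else None
            )
            for name in ("probes", "cpg_map", "rois", "gene_sets", "phenotypes", "groups"):
                p = getattr(config, name)
                if p:
                    inputs[name] = sha256_of(p)

            noise_sd = config.noise_sd

        stage = "estimate"
        regions, meth = estimate_matrix(
            probes, sample_ids, link, grid_step=config.grid_step, noise_sd=noise_sd
        )
        write_methylation_matrix(regions, meth, outdir / "region_estimates.tsv")
        outputs["region_estimates.tsv"] = sha256_of(outdir / "region_estimates.tsv")

        stage = "screen"
        design = GroupDesign.from_labels(groups)
        dmr_table = call_dmrs(
            meth,
            design,
            thresholds=config.thresholds,
            regions=regions,
            informative=~regions["uninformative"].to_numpy(),
        )
        _write_tsv(dmr_table, outdir / "dmr_table.tsv")
        outputs["dmr_table.tsv"] = sha256_of(outdir / "dmr_table.tsv")

        stage = "enrich"
        rois = rois_from_frame(rois_df)
        dmroi_table = call_dmrois(dmr_table, rois, meth, design)
        _write_tsv(dmroi_table, outdir / "dmroi_table.tsv")
        outputs["dmroi_table.tsv"] = sha256_of(outdir / "dmroi_table.tsv")

        if gene_sets:
            dmroi_genes = dmroi_table.loc[dmroi_table["is_dmroi"], "gene_id"]
            gs = geneset_enrichment(dmroi_genes, gene_sets, rois_df["gene_id"])
            _write_tsv(gs, outdir / "geneset_table.tsv")
            outputs["geneset_table.tsv"] = sha256_of(outdir / "geneset_table.tsv")
        else:
            log.warning("no gene sets supplied; enrichment-by-set stage skipped")

        if subjects is not None:
            stage = "associate"
            cpg_cols = [c for c in subjects.columns if c.startswith("CpG")]
            assoc = associate_all(
                subjects, cpg_cols, ["outcome"], tiers=list(config.tiers)
            )
            _write_tsv(assoc, outdir / "association_table.tsv")
            outputs["association_table.tsv"] = sha256_of(outdir / "association_table.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "methscreen",
        "version": __version__,
        "seed": config.seed,
        "inputs": inputs,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def assigned_rois_of_planted(cohort, rois_df: pd.DataFrame) -> list[int]:
    """Indices of ROIs (rows of rois_df) containing a planted window."""
    w = cohort.config.windows_per_roi
    planted_windows = cohort.true_dmr_mask.nonzero()[0]
    return sorted({int(i // w) for i in planted_windows})
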