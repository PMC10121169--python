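"""End-to-end orchestration: simulate -> segment -> quantify -> statistics.

Each run writes its tables into an output directory together with a JSON
manifest (config hash, input checksums, seed, per-stage row counts) so a
run can be reproduced exactly.  All randomness flows from the single run
seed; derived stage seeds are recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .particles import ParticleConfig, detect_particles, particles_frame, phagocytic_index, assemble_uptake_curves
from .puncta import PunctaConfig, classify_flux, count_puncta, flux_frame, nuclear_localization, nuclear_loc_frame
from .segmentation import SegmentationConfig, detect_nuclei, expand_zones
from .stats import call_interactors, permutation_fdr, preprocess_tmt, top_set
from .synthgen import ImagingSimConfig, TmtTable, simulate_field

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    assay: str  # simulate | phago | puncta | flux | nfkb | interactome
    images_dir: str | None = None
    metadata_csv: str | None = None
    table_path: str | None = None
    out_dir: str = "phagoquant_out"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    particle: ParticleConfig = field(default_factory=ParticleConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    imaging_sim: ImagingSimConfig = field(default_factory=ImagingSimConfig)
    n_fields: int = 5
    genotypes: tuple[str, ...] = ("mutant", "isogenic")
    fdr_levels: tuple[float, ...] = (0.01, 0.05)
    n_permutations: int = 1000
    s0: float = 0.0
    control_cols: tuple[str, ...] = ("control_1", "control_2", "control_3", "control_4")
    gfp_cols: tuple[str, ...] = ("gfp_1", "gfp_2", "gfp_3", "gfp_4")
    rng_seed: int = 0
    log_level: str = "INFO"


def _config_hash(config: RunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _segment(image, config: RunConfig):
    nuclei = detect_nuclei(image.channels["nuclear"], config.segmentation)
    zones = expand_zones(nuclei, image.shape, config.segmentation)
    return nuclei, zones


def run_assay(config: RunConfig) -> Path:
    """Run one assay end to end; returns the output directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "software_version": __version__,
        "seed": config.rng_seed,
        "assay": config.assay,
        "inputs": {},
        "row_counts": {},
        "stage_seeds": {},
    }
    runner = {
        "simulate": _run_simulate,
        "phago": _run_phago,
        "puncta": _run_puncta,
        "flux": _run_flux,
        "nfkb": _run_nfkb,
        "interactome": _run_interactome,
    }.get(config.assay)
    if runner is None:
        raise ValueError(f"unknown assay {config.assay!r}")
    runner(config, out, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _run_simulate(config: RunConfig, out: Path, manifest: dict) -> None:
    rng = np.random.default_rng(config.rng_seed)
    images_dir = out / "images"
    images_dir.mkdir(exist_ok=True)
    meta_rows = []
    for genotype in config.genotypes:
        for t in config.imaging_sim.time_grid:
            for f in range(config.n_fields):
                seed = int(rng.integers(2**31))
                sim = dataclasses.replace(config.imaging_sim, rng_seed=seed)
                image, truth = simulate_field(sim, genotype, t)
                name = f"{genotype}_t{int(t):03d}_f{f:02d}"
                pio.write_field(image, images_dir / f"{name}.tiff")
                pio.write_table(truth.nuclei, images_dir / f"{name}_truth_nuclei.csv")
                pio.write_table(truth.particles, images_dir / f"{name}_truth_particles.csv")
                meta_rows.append(
                    {
                        "image": f"{name}.tiff",
                        "genotype": genotype,
                        "condition": "none",
                        "timepoint": float(t),
                        "field": f,
                        "stage_seed": seed,
                    }
                )
                manifest["stage_seeds"][name] = seed
    meta = pd.DataFrame(meta_rows)
    pio.write_table(meta, out / "metadata.csv")
    manifest["row_counts"]["metadata"] = len(meta)


def _load_metadata(config: RunConfig) -> pd.DataFrame:
    if config.metadata_csv is None:
        raise ValueError("metadata_csv is required for this assay")
    meta = pio.read_table(config.metadata_csv)
    required = {"image", "genotype", "timepoint"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required column(s): {sorted(missing)}")
    if "condition" not in meta.columns:
        meta["condition"] = "none"
    return meta


def _run_phago(config: RunConfig, out: Path, manifest: dict) -> None:
    meta = _load_metadata(config)
    images_dir = Path(config.images_dir or ".")
    all_particles = []
    records = []
    for _, row in meta.iterrows():
        path = images_dir / row["image"]
        manifest["inputs"][row["image"]] = _checksum(path)
        image = pio.read_field(path)
        nuclei, zones = _segment(image, config)
        n_accepted = sum(n.accepted for n in nuclei)
        particles = detect_particles(image.channels["phrodo"], zones, config.particle)
        pf = particles_frame(particles)
        pf.insert(0, "image", row["image"])
        all_particles.append(pf)
        n_retained = int(pf["retained"].sum()) if len(pf) else 0
        if n_accepted == 0:
            logger.warning("field %s has no accepted nuclei; excluded", row["image"])
            continue
        records.append(
            {
                "image": row["image"],
                "genotype": row["genotype"],
                "condition": row["condition"],
                "timepoint": float(row["timepoint"]),
                "n_nuclei": n_accepted,
                "n_spots": n_retained,
                "beads_per_cell": phagocytic_index(n_accepted, n_retained),
            }
        )
    non_empty = [pf for pf in all_particles if len(pf)]
    particles_table = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=["image"])
    )
    record_table = pd.DataFrame(records)
    curves = assemble_uptake_curves(record_table)
    pio.write_table(particles_table, out / "particles.csv")
    pio.write_table(record_table, out / "uptake_records.csv")
    pio.write_table(curves, out / "uptake_curves.csv")
    manifest["row_counts"].update(
        {"particles": len(particles_table), "uptake_records": len(record_table), "uptake_curves": len(curves)}
    )


def _run_puncta(config: RunConfig, out: Path, manifest: dict) -> None:
    meta = _load_metadata(config)
    images_dir = Path(config.images_dir or ".")
    rows = []
    for _, row in meta.iterrows():
        image = pio.read_field(images_dir / row["image"])
        nuclei, zones = _segment(image, config)
        channel_name = next(n for n in image.channel_order if n != "nuclear")
        counts, _ = count_puncta(image.channels[channel_name], zones, config.puncta)
        for cell, n in sorted(counts.items()):
            rows.append({"image": row["image"], "cell_id": cell, "n_puncta": n})
    table = pd.DataFrame(rows)
    pio.write_table(table, out / "puncta_counts.csv")
    manifest["row_counts"]["puncta_counts"] = len(table)


def _run_flux(config: RunConfig, out: Path, manifest: dict) -> None:
    meta = _load_metadata(config)
    images_dir = Path(config.images_dir or ".")
    frames = []
    for _, row in meta.iterrows():
        image = pio.read_field(images_dir / row["image"])
        nuclei, zones = _segment(image, config)
        _, gfp_tab = count_puncta(image.channels["gfp"], zones, config.puncta)
        _, mch_tab = count_puncta(image.channels["mcherry"], zones, config.puncta)
        results = classify_flux(gfp_tab, mch_tab, config.puncta.match_radius)
        f = flux_frame(results)
        f.insert(0, "image", row["image"])
        frames.append(f)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    pio.write_table(table, out / "flux_results.csv")
    manifest["row_counts"]["flux_results"] = len(table)


def _run_nfkb(config: RunConfig, out: Path, manifest: dict) -> None:
    meta = _load_metadata(config)
    images_dir = Path(config.images_dir or ".")
    frames = []
    for _, row in meta.iterrows():
        image = pio.read_field(images_dir / row["image"])
        nuclei, zones = _segment(image, config)
        results = nuclear_localization(image.channels["nfkb"], nuclei, zones, config.puncta)
        f = nuclear_loc_frame(results)
        f.insert(0, "image", row["image"])
        frames.append(f)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    pio.write_table(table, out / "nfkb_results.csv")
    manifest["row_counts"]["nfkb_results"] = len(table)


def _run_interactome(config: RunConfig, out: Path, manifest: dict) -> None:
    if config.table_path is None:
        raise ValueError("table_path is required for the interactome assay")
    path = Path(config.table_path)
    manifest["inputs"][path.name] = _checksum(path)
    frame = pio.read_table(path)
    table = TmtTable(
        frame=frame, control_cols=list(config.control_cols), gfp_cols=list(config.gfp_cols)
    )
    log2 = preprocess_tmt(table)
    result = permutation_fdr(
        log2,
        gfp_cols=list(config.gfp_cols),
        levels=tuple(config.fdr_levels),
        n_permutations=config.n_permutations,
        s0=config.s0,
        rng_seed=config.rng_seed,
    )
    interactors = call_interactors(result.table, fold_min=2.0, fdr_level=min(config.fdr_levels))
    top50 = top_set(result.table, fold_min=3.0, k=50)
    pio.write_table(result.table, out / "enrichment_results.csv")
    pio.write_table(result.fdr_curve, out / "fdr_curve.csv")
    pio.write_table(interactors, out / "interactors.csv")
    pio.write_table(top50, out / "top50.csv")
    manifest["row_counts"].update(
        {
            "enrichment_results": len(result.table),
            "interactors": len(interactors),
            "top50": len(top50),
        }
    )


def report(out_dir: str | Path) -> list[Path]:
    """Render summary plots for whatever stage outputs exist in a run
    directory: uptake curves (mean +- SEM), a volcano of the enrichment
    results, and puncta boxplots.  Missing stages are skipped with a
    warning."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written: list[Path] = []

    curves_path = out / "uptake_curves.csv"
    if curves_path.exists():
        curves = pd.read_csv(curves_path)
        fig, ax = plt.subplots()
        for genotype, sub in curves.groupby("genotype"):
            ax.errorbar(sub["timepoint"], sub["mean"], yerr=sub["sem"], label=str(genotype), capsize=3)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("beads/cell")
        ax.legend()
        fig.savefig(out / "uptake_curves.png", dpi=120)
        plt.close(fig)
        written.append(out / "uptake_curves.png")
    else:
        logger.warning("no uptake curves to plot")

    enrich_path = out / "enrichment_results.csv"
    if enrich_path.exists():
        res = pd.read_csv(enrich_path)
        fig, ax = plt.subplots()
        sig_col = next((c for c in res.columns if c.startswith("significant_1")), None)
        with np.errstate(divide="ignore"):
            neglog = -np.log10(np.clip(res["p"], 1e-300, None))
        hits = res[sig_col] & (res["log2fc"] > 1.0) if sig_col is not None else np.zeros(len(res), bool)
        ax.scatter(res["log2fc"], neglog, s=6, c="grey", label="background")
        if hits.any():
            ax.scatter(res.loc[hits, "log2fc"], neglog[hits], s=10, c="crimson", label="interactors")
        else:
            ax.annotate("no significant proteins", xy=(0.5, 0.5), xycoords="axes fraction", ha="center")
        ax.set_xlabel("log2 fold enrichment (GFP - control)")
        ax.set_ylabel("-log10 p")
        ax.legend()
        fig.savefig(out / "volcano.png", dpi=120)
        plt.close(fig)
        written.append(out / "volcano.png")
    else:
        logger.warning("no enrichment results to plot")

    puncta_path = out / "puncta_counts.csv"
    if puncta_path.exists():
        counts = pd.read_csv(puncta_path)
        fig, ax = plt.subplots()
        counts.boxplot(column="n_puncta", by="image", ax=ax, rot=90)
        ax.set_ylabel("puncta per cell")
        fig.suptitle("")
        fig.tight_layout()
        fig.savefig(out / "puncta_boxplot.png", dpi=120)
        plt.close(fig)
        written.append(out / "puncta_boxplot.png")
    return written
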