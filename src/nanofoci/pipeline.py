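"""End-to-end orchestration: config, staged execution, report emission.

A run ingests one cohort of nuclei (synthetic scenes, orte files, or raw
frame stacks), then executes masking, clustering, distance statistics,
co-localization, topology and group statistics, and writes a fully
reproducible report: identical config + seed gives bit-identical outputs.
The global seed is fanned out to per-nucleus child seeds through a
counter scheme (`SeedSequence(seed).generate_state`), so toggling stages
does not perturb the others.
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

from . import __version__
from .clustering import ClusterParams, clusters_to_frame, dbscan, summarize_nucleus
from .coloc import (
    ColocParams,
    cluster_overlap,
    colocalize_both_directions,
    density_in_clusters,
)
from .distances import detect_peaks, pairwise_distance_histogram
from .io_masks import BinaryMask, OrteMatrix, apply_mask, read_mask, read_orte
from .localization import DetectionParams, FrameStack, localize_stack
from .stats import GroupComparison, compare_groups
from .synthetic import SceneParams, generate_scene, sample_localizations
from .topology import (
    Barcode,
    alpha_persistence,
    barcode_to_rows,
    cross_heatmap,
    first_generation_heatmap,
    second_generation_heatmap,
)

logger = logging.getLogger(__name__)

MODES = ("synthetic", "orte-files", "frame-stacks")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration; exactly one input mode."""

    mode: str = "synthetic"
    seed: int = 0
    n_nuclei: int = 5
    scene: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    coloc_thresholds_nm: tuple = (95.0, 50.0, 20.0)
    histogram: dict = field(default_factory=lambda: {"bin_width_nm": 10.0, "max_distance_nm": 1000.0})
    topology: dict = field(
        default_factory=lambda: {"alpha_max_nm": 500.0, "max_points": 600, "granularity": "foci"}
    )
    compare_to_control: bool = False
    inputs: list = field(default_factory=list)
    labels: tuple = ("ch1", "ch2")

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "synthetic":
            if self.inputs:
                raise ConfigError("synthetic mode must not define file inputs")
            if self.n_nuclei < 1:
                raise ConfigError("n_nuclei must be >= 1")
            SceneParams(**self.scene).validate()  # fail fast on bad blocks
        else:
            if not self.inputs:
                raise ConfigError(f"{self.mode} mode requires a non-empty 'inputs' list")
        ClusterParams(**self.cluster)
        DetectionParams(**self.detection)
        for t in self.coloc_thresholds_nm:
            ColocParams(float(t))
        if self.topology.get("granularity", "foci") not in ("nucleus", "foci", "clusters"):
            raise ConfigError("topology.granularity must be nucleus|foci|clusters")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = dict(raw)
        if "coloc_thresholds_nm" in cfg:
            cfg["coloc_thresholds_nm"] = tuple(float(t) for t in cfg["coloc_thresholds_nm"])
        if "labels" in cfg:
            cfg["labels"] = tuple(cfg["labels"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coloc_thresholds_nm"] = list(self.coloc_thresholds_nm)
        d["labels"] = list(self.labels)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class NucleusResult:
    nucleus_id: str
    summary: pd.DataFrame
    histograms: dict
    peaks: dict
    coloc: pd.DataFrame
    barcodes: dict[str, Barcode]
    cluster_overlap_pct: float | None
    density_in_a_clusters: float | None
    cluster_tables: dict[str, pd.DataFrame]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    seed: int
    version: str
    nuclei: list[NucleusResult]
    gen1_heatmaps: dict
    gen2_heatmaps: dict
    comparisons: list[GroupComparison]
    logs: list[str] = field(default_factory=list)

    def summary_table(self) -> pd.DataFrame:
        frames = []
        for nuc in self.nuclei:
            df = nuc.summary.copy()
            df.insert(0, "nucleus", nuc.nucleus_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def coloc_table(self) -> pd.DataFrame:
        frames = []
        for nuc in self.nuclei:
            df = nuc.coloc.copy()
            df.insert(0, "nucleus", nuc.nucleus_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _child_seeds(seed: int, n: int) -> list[int]:
    # documented counter scheme: one uint32 per nucleus, irradiated cohort
    # first, then (if requested) the control cohort
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(2 * n)]


def _topology_points(orte_nuc, orte_foci, granularity, cluster_params):
    if granularity == "nucleus":
        return orte_nuc.xy
    if granularity == "foci":
        return orte_foci.xy
    clusters, _ = dbscan(orte_nuc.xy, cluster_params)
    if not clusters:
        return np.zeros((0, 2))
    member = np.concatenate([c.members for c in clusters])
    return orte_nuc.xy[np.sort(member)]


def _process_nucleus(
    nucleus_id: str,
    ortes: dict[str, OrteMatrix],
    nucleus_mask: BinaryMask,
    foci_mask: BinaryMask,
    config: RunConfig,
    rng: np.random.Generator,
) -> NucleusResult:
    cluster_params = ClusterParams(**config.cluster)
    masks = {"nucleus": nucleus_mask, "foci": foci_mask}
    label_a, label_b = config.labels

    nuc_masked = {lab: apply_mask(o, nucleus_mask) for lab, o in ortes.items()}
    foci_masked = {lab: apply_mask(o, foci_mask) for lab, o in ortes.items()}

    summary = summarize_nucleus(ortes, masks, cluster_params)

    histograms, peaks = {}, {}
    for lab, orte in nuc_masked.items():
        if len(orte) >= 2:
            hist = pairwise_distance_histogram(orte.xy, **config.histogram)
            histograms[lab] = hist
            peaks[lab] = detect_peaks(hist)

    coloc_rows = []
    if len(nuc_masked[label_a]) and len(nuc_masked[label_b]):
        for thr in config.coloc_thresholds_nm:
            fwd, rev = colocalize_both_directions(
                nuc_masked[label_a], nuc_masked[label_b], ColocParams(float(thr))
            )
            for res, direction in ((fwd, f"{label_a}->{label_b}"), (rev, f"{label_b}->{label_a}")):
                coloc_rows.append(
                    {
                        "threshold_nm": res.threshold_nm,
                        "direction": direction,
                        "n_a": res.n_a,
                        "n_coloc": res.n_coloc,
                        "fraction_pct": res.fraction_pct,
                    }
                )
    coloc = pd.DataFrame(coloc_rows)

    clusters_a, _ = dbscan(nuc_masked[label_a].xy, cluster_params)
    clusters_b, _ = dbscan(nuc_masked[label_b].xy, cluster_params)
    overlap = cluster_overlap(clusters_a, clusters_b)
    density_b_in_a = density_in_clusters(nuc_masked[label_b], clusters_a)
    cluster_tables = {label_a: clusters_to_frame(clusters_a), label_b: clusters_to_frame(clusters_b)}

    topo_cfg = config.topology
    barcodes = {}
    for lab in config.labels:
        pts = _topology_points(
            nuc_masked[lab], foci_masked[lab], topo_cfg.get("granularity", "foci"), cluster_params
        )
        max_points = int(topo_cfg.get("max_points", 600))
        if len(pts) > max_points:
            pts = pts[rng.choice(len(pts), max_points, replace=False)]
        if len(pts) >= 1:
            barcodes[lab] = alpha_persistence(pts, float(topo_cfg.get("alpha_max_nm", 500.0)))

    return NucleusResult(
        nucleus_id=nucleus_id,
        summary=summary,
        histograms=histograms,
        peaks=peaks,
        coloc=coloc,
        barcodes=barcodes,
        cluster_overlap_pct=overlap,
        density_in_a_clusters=density_b_in_a,
        cluster_tables=cluster_tables,
    )


def _load_nucleus_inputs(entry: dict, config: RunConfig):
    label_a, label_b = config.labels
    nucleus_mask = read_mask(entry["nucleus_mask"])
    foci_mask = read_mask(entry["foci_mask"]) if entry.get("foci_mask") else nucleus_mask
    if config.mode == "orte-files":
        ortes = {
            label_a: read_orte(entry["orte_ch1"], channel=label_a),
            label_b: read_orte(entry["orte_ch2"], channel=label_b),
        }
    else:  # frame-stacks
        import tifffile

        detection = DetectionParams(**config.detection)
        ortes = {}
        for lab, key in ((label_a, "stack_ch1"), (label_b, "stack_ch2")):
            frames = tifffile.imread(entry[key])
            stack = FrameStack(frames, pixel_size_nm=float(entry.get("pixel_size_nm", 100.0)))
            ortes[lab] = localize_stack(stack, detection, channel=lab)
    return ortes, nucleus_mask, foci_mask


def _synthetic_nucleus(config: RunConfig, scene_seed: int):
    params = SceneParams(**{**config.scene, "seed": scene_seed})
    scene = generate_scene(params)
    ortes = {
        config.labels[0]: sample_localizations(scene, 1),
        config.labels[1]: sample_localizations(scene, 2),
    }
    return ortes, scene.nucleus_mask, scene.foci_mask


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; a nucleus failing one stage is excluded from that
    stage's aggregates (logged) but still contributes to the others."""
    logs: list[str] = []
    n = config.n_nuclei if config.mode == "synthetic" else len(config.inputs)
    seeds = _child_seeds(config.seed, max(n, 1))

    nuclei: list[NucleusResult] = []
    for i in range(n):
        rng = np.random.default_rng([config.seed, 13, i])
        if config.mode == "synthetic":
            ortes, nuc_mask, foci_mask = _synthetic_nucleus(config, seeds[i])
            nucleus_id = f"syn{i:03d}"
        else:
            entry = config.inputs[i]
            ortes, nuc_mask, foci_mask = _load_nucleus_inputs(entry, config)
            nucleus_id = str(entry.get("id", f"nuc{i:03d}"))
        try:
            nuclei.append(
                _process_nucleus(nucleus_id, ortes, nuc_mask, foci_mask, config, rng)
            )
        except Exception as exc:
            msg = f"nucleus {nucleus_id} failed: {exc!r}"
            logger.error(msg)
            logs.append(msg)

    label_a, label_b = config.labels
    gen1, gen2 = {}, {}
    for dim, dim_name in ((0, "components"), (1, "holes")):
        bars_a = [nuc.barcodes[label_a] for nuc in nuclei if label_a in nuc.barcodes]
        bars_b = [nuc.barcodes[label_b] for nuc in nuclei if label_b in nuc.barcodes]
        maps = {}
        if len(bars_a) >= 2:
            maps[(label_a, label_a)] = first_generation_heatmap(bars_a, dim)
        if len(bars_b) >= 2:
            maps[(label_b, label_b)] = first_generation_heatmap(bars_b, dim)
        if bars_a and bars_b:
            maps[(label_a, label_b)] = cross_heatmap(bars_a, bars_b, dim)
        if maps:
            gen1[dim_name] = maps
            gen2[dim_name] = second_generation_heatmap(maps, list(config.labels))

    comparisons: list[GroupComparison] = []
    if config.compare_to_control and config.mode == "synthetic":
        control_cfg = dict(config.scene)
        control_cfg["coloc_fraction"] = 0.0
        control_seeds = seeds[n : 2 * n] if len(seeds) >= 2 * n else seeds
        direction = f"{label_b}->{label_a}"
        for thr in config.coloc_thresholds_nm:
            irradiated, control = [], []
            for i in range(n):
                for cohort, values in (("irr", irradiated), ("ctl", control)):
                    if cohort == "irr":
                        nuc = nuclei[i] if i < len(nuclei) else None
                        if nuc is not None and len(nuc.coloc):
                            sel = nuc.coloc.query(
                                "threshold_nm == @thr and direction == @direction"
                            )
                            if len(sel):
                                values.append(float(sel["fraction_pct"].iloc[0]))
                    else:
                        params = SceneParams(**{**control_cfg, "seed": control_seeds[i]})
                        scene = generate_scene(params)
                        o1 = apply_mask(sample_localizations(scene, 1), scene.nucleus_mask)
                        o2 = apply_mask(sample_localizations(scene, 2), scene.nucleus_mask)
                        if len(o1) and len(o2):
                            from .coloc import colocalize_points

                            res = colocalize_points(o2, o1, ColocParams(float(thr)))
                            values.append(res.fraction_pct)
            if len(irradiated) >= 3 and len(control) >= 3:
                cmp = compare_groups(
                    irradiated, control, label_a=f"irradiated@{thr:g}nm", label_b="control"
                )
                comparisons.append(cmp)

    return RunReport(
        config=config.to_dict(),
        config_hash=config.config_hash,
        seed=config.seed,
        version=__version__,
        nuclei=nuclei,
        gen1_heatmaps=gen1,
        gen2_heatmaps=gen2,
        comparisons=comparisons,
        logs=logs,
    )


# ---------------------------------------------------------------------------
# report emission


def _backup_then_open(path: Path):
    if path.exists():
        bak = path.with_suffix(path.suffix + ".bak")
        if bak.exists():
            bak.unlink()
        path.rename(bak)
    return open(path, "w")


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with _backup_then_open(path) as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _heatmap_frame(hm) -> pd.DataFrame:
    return pd.DataFrame(hm.values, index=hm.row_labels, columns=hm.col_labels)


def emit_report(report: RunReport, outdir, figures: bool = False) -> list[Path]:
    """Write all report files; returns the list of paths written.

    Every CSV starts with a provenance comment line carrying the config
    hash and seed.  Existing files are backed up to ``*.bak`` first.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"config_hash={report.config_hash} seed={report.seed} nanofoci={report.version}"
    written: list[Path] = []

    def csv(df, name):
        path = outdir / name
        _write_csv(df, path, header)
        written.append(path)

    csv(report.summary_table(), "summary.csv")
    csv(report.coloc_table(), "coloc.csv")

    hist_rows, peak_obj, bar_rows, overlap_rows = [], {}, [], []
    for nuc in report.nuclei:
        for lab, hist in nuc.histograms.items():
            for left, right, f in zip(
                hist.bin_edges_nm[:-1], hist.bin_edges_nm[1:], hist.rel_freq
            ):
                hist_rows.append(
                    {
                        "nucleus": nuc.nucleus_id,
                        "label": lab,
                        "bin_left_nm": left,
                        "bin_right_nm": right,
                        "rel_freq": f,
                    }
                )
        peak_obj[nuc.nucleus_id] = {
            lab: {
                "positions_nm": pk.positions_nm.tolist(),
                "heights": pk.heights.tolist(),
                "fwhm_nm": pk.fwhm_nm.tolist(),
                "spacings_nm": pk.spacings_nm.tolist(),
            }
            for lab, pk in nuc.peaks.items()
        }
        for lab, bc in nuc.barcodes.items():
            for dim, birth, death in barcode_to_rows(bc):
                bar_rows.append(
                    {
                        "nucleus": nuc.nucleus_id,
                        "label": lab,
                        "dim": dim,
                        "birth_nm": birth,
                        "death_nm": death,
                    }
                )
        overlap_rows.append(
            {
                "nucleus": nuc.nucleus_id,
                "cluster_overlap_pct": np.nan
                if nuc.cluster_overlap_pct is None
                else nuc.cluster_overlap_pct,
                "density_in_a_clusters_per_um2": np.nan
                if nuc.density_in_a_clusters is None
                else nuc.density_in_a_clusters,
            }
        )
    csv(pd.DataFrame(hist_rows), "histograms.csv")
    csv(pd.DataFrame(bar_rows), "barcodes.csv")
    csv(pd.DataFrame(overlap_rows), "overlap.csv")

    for dim_name, maps in report.gen1_heatmaps.items():
        for (la, lb), hm in maps.items():
            df = _heatmap_frame(hm).reset_index(names="sample")
            csv(df, f"heatmap_gen1_{la}_{lb}_{dim_name}.csv")
    for dim_name, hm in report.gen2_heatmaps.items():
        df = _heatmap_frame(hm).reset_index(names="label")
        csv(df, f"heatmap_gen2_{dim_name}.csv")

    provenance = {"config_hash": report.config_hash, "seed": report.seed,
                  "version": report.version, "config": report.config}
    json_objects = {
        "peaks.json": {"provenance": provenance, "peaks": peak_obj},
        "comparisons.json": {
            "provenance": provenance,
            "comparisons": [dataclasses.asdict(c) for c in report.comparisons],
        },
        "report.json": {"provenance": provenance, "n_nuclei": len(report.nuclei),
                        "logs": report.logs},
    }
    for name, obj in json_objects.items():
        path = outdir / name
        with _backup_then_open(path) as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
        written.append(path)

    with _backup_then_open(outdir / "summary.txt") as fh:
        fh.write(f"nanofoci run report\n# {header}\n")
        fh.write(f"nuclei analyzed: {len(report.nuclei)}\n")
        for cmp in report.comparisons:
            fh.write(
                f"{cmp.label_a} vs {cmp.label_b}: p={cmp.p_value:.4g} {cmp.annotation}\n"
            )
        for line in report.logs:
            fh.write(f"WARN {line}\n")
    written.append(outdir / "summary.txt")

    if figures:
        written.extend(_emit_figures(report, outdir))
    return written


def _emit_figures(report: RunReport, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for nuc in report.nuclei[:1]:  # representative nucleus
        if not nuc.histograms:
            continue
        fig, ax = plt.subplots()
        for lab, hist in nuc.histograms.items():
            ax.plot(hist.bin_centers_nm, hist.rel_freq, label=lab)
        ax.set_xlabel("pairwise distance (nm)")
        ax.set_ylabel("relative frequency")
        ax.legend()
        path = outdir / f"histogram_{nuc.nucleus_id}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    for dim_name, hm in report.gen2_heatmaps.items():
        fig, ax = plt.subplots()
        im = ax.imshow(hm.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(hm.col_labels)), hm.col_labels)
        ax.set_yticks(range(len(hm.row_labels)), hm.row_labels)
        fig.colorbar(im, ax=ax, label="S")
        path = outdir / f"heatmap_gen2_{dim_name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
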