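"""End-to-end analysis pipeline: images → particles → g(r) → quadrat verdict.

One call runs detection, the height histogram, the pair-correlation
estimate, and the quadrat Poisson analysis for each input frame, then pools
the per-frame verdicts by majority (the dispersion index of the pooled
counts is reported alongside).  Frames with fewer than two detected
particles are skipped with a warning and listed in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .datatypes import DetectionConfig, PointPattern
from .detect import detect_particles, to_point_pattern
from .io import read_heightmap, read_point_pattern, write_particles
from .quadrat import analyze_quadrats
from .rdf import RDFConfig, compute_rdf, estimate_exclusion_radius

log = logging.getLogger("colloid2d")

try:  # Python 3.11+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable parameterisation of a full pipeline run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    pixel_size: Optional[float] = None
    rdf_r_max: float = 2000.0
    rdf_bin_width: Optional[float] = None
    rdf_edge_correction: str = "isotropic"
    quadrat_min_mean: float = 25.0
    confidence: float = 0.95
    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        det = DetectionConfig(**raw.pop("detection", {}))
        return cls(detection=det, **raw)

    def to_toml(self, path: str | Path) -> None:
        d = asdict(self)
        det = d.pop("detection")
        lines = []
        for k, v in d.items():
            if v is None:
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
        lines.append("[detection]")
        for k, v in det.items():
            lines.append(f"{k} = {_toml_value(v)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    return repr(v)


def default_bin_width(pixel_size: float, r_max: float) -> float:
    """Default g(r) bin: no finer than a pixel, at most 200 bins."""
    return max(pixel_size, r_max / 200.0)


def analyze_pattern(pattern: PointPattern, config: PipelineConfig,
                    pixel_size: float = 1.0) -> dict:
    """Run g(r) + quadrat analysis on one point pattern; returns a report."""
    bw = config.rdf_bin_width or default_bin_width(pixel_size, config.rdf_r_max)
    rdf_cfg = RDFConfig(r_max=config.rdf_r_max, bin_width=bw,
                        edge_correction=config.rdf_edge_correction)
    rdf = compute_rdf(pattern, rdf_cfg)
    excl = estimate_exclusion_radius(rdf)
    quad = analyze_quadrats(pattern, min_mean_count=config.quadrat_min_mean,
                            confidence=config.confidence)
    return {
        "n_points": pattern.n,
        "window_nm": list(pattern.window),
        "density_per_nm2": pattern.density,
        "rdf": {
            "r_nm": rdf.r.tolist(),
            "g": rdf.g.tolist(),
            "pair_counts": rdf.pair_counts.tolist(),
        },
        "exclusion_radius_nm": excl,
        "quadrat": {
            "n_regions": int(quad.counts.size),
            "grid_shape": list(quad.grid_shape),
            "lambda_hat": quad.lambda_hat,
            "variance": quad.variance,
            "dispersion_index": quad.dispersion_index,
            "gof_pvalue": quad.gof_pvalue,
            "regime": quad.regime,
        },
    }


def run_pipeline(inputs: Sequence[str | Path], config: PipelineConfig,
                 window: Optional[tuple[float, float]] = None) -> dict:
    """Analyze a batch of images (or particle CSVs) and pool the verdicts.

    Image files need ``config.pixel_size``; CSV particle lists need
    ``window``.  Returns the machine-readable report; per-frame outputs are
    written under ``config.output_dir`` when set.
    """
    if not inputs:
        raise ValueError("at least one input file is required")
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    frames = []
    skipped = []
    total_particles = 0
    for path in inputs:
        path = Path(path)
        try:
            if path.suffix.lower() == ".csv":
                if window is None:
                    raise ValueError("window is required for CSV input")
                pattern = read_point_pattern(path, window)
                particles = None
            else:
                if config.pixel_size is None:
                    raise ValueError("pixel_size is required for image input")
                hmap = read_heightmap(path, pixel_size=config.pixel_size)
                particles = detect_particles(hmap, config.detection)
                pattern = to_point_pattern(particles, hmap)
        except Exception as exc:
            raise type(exc)(f"{path}: {exc}") from exc
        if pattern.n < 2:
            log.warning("skipping %s: fewer than 2 particles detected", path)
            skipped.append(str(path))
            continue
        px = config.pixel_size or 1.0
        report = analyze_pattern(pattern, config, pixel_size=px)
        report["file"] = str(path)
        if particles is not None and out_dir:
            write_particles(particles, out_dir / f"{path.stem}.particles.csv")
        if pattern.heights is not None and len(pattern.heights):
            edges, counts = height_histogram_from_heights(pattern.heights)
            report["height_histogram"] = {
                "edges_nm": edges.tolist(), "counts": counts.tolist()}
        frames.append(report)
        total_particles += pattern.n

    if not frames:
        raise ValueError("no input frame yielded at least 2 particles")

    verdicts = [f["quadrat"]["regime"] for f in frames]
    pooled_verdict = max(set(verdicts), key=verdicts.count)
    lam = np.array([f["quadrat"]["lambda_hat"] for f in frames])
    var = np.array([f["quadrat"]["variance"] for f in frames])
    nreg = np.array([f["quadrat"]["n_regions"] for f in frames])
    pooled_dispersion = float((var * (nreg - 1)).sum()
                              / (lam * (nreg - 1)).sum())
    report = {
        "frames": frames,
        "skipped": skipped,
        "n_frames": len(frames),
        "total_particles": total_particles,
        "pooled_regime": pooled_verdict,
        "pooled_dispersion_index": pooled_dispersion,
        "seed": config.seed,
    }
    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def height_histogram_from_heights(heights: np.ndarray,
                                  bin_width: float = 0.25
                                  ) -> tuple[np.ndarray, np.ndarray]:
    heights = np.asarray(heights, dtype=float)
    n_bins = max(1, int(np.ceil(heights.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(heights, bins=edges)
    return edges, counts
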