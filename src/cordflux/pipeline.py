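"""End-to-end orchestration: simulate -> quantify -> summarize.

A :class:`RunConfig` carries every stage parameter, round-trips
losslessly through a ``key=value`` config file, and a run writes all
outputs plus a machine-readable manifest (resolved config, seed,
package version) into a run directory.  Stages execute in dependency
order; requesting an analysis stage without its input raises
:class:`DependencyError` naming the missing stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .core import (Image, LambdaStack, TimeLapse, read_tiff_image,
                   read_tiff_stack, write_tiff_image, write_tiff_stack)
from .coloc import adjacency_fraction, pearson_coloc, tolerance_coloc
from .kymo import (build_kymograph, classify_track, detect_and_link,
                   tracks_to_dataframe, transport_summary)
from .puncta import auto_threshold, detect_puncta, puncta_density
from .simdata import (SimImageSpec, SimMovieSpec, VesicleSpec,
                      make_lambda_stack, make_movie, make_puncta_image,
                      make_two_channel_image)
from .unmix import (default_autofluorescence_profile, default_gfp_profile,
                    unmix)

__all__ = ["RunConfig", "DependencyError", "run_pipeline"]

ALL_STAGES = ("simulate", "puncta", "coloc", "unmix", "kymo")


class DependencyError(RuntimeError):
    """An analysis stage is missing its upstream input."""


@dataclass
class RunConfig:
    """Full, flat configuration for a pipeline run."""

    stages: str = "simulate,puncta,coloc,unmix,kymo"
    seed: int = 0
    out_dir: str = "cordflux_run"

    # synthetic image geometry
    width_px: int = 512
    height_px: int = 64
    pixel_size_um: float = 0.16
    n_puncta: int = 12
    punctum_sigma_um: float = 0.25
    punctum_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 2.0

    # puncta detection
    threshold_method: str = "otsu"
    threshold_percentile: float = 0.05
    min_area: int = 4
    connectivity: int = 8

    # colocalization
    coloc_fraction: float = 0.5
    offset_um: float = 0.0
    coloc_tolerance: float = 0.1

    # spectral unmixing
    lambda_noise_sd: float = 0.01

    # movie / kymograph
    frames: int = 150
    frame_rate_hz: float = 3.1
    cord_length_um: float = 80.0
    n_anterograde: int = 3
    n_retrograde: int = 2
    speed_um_per_s: float = 1.5
    stationary_n: int = 2
    move_px: float = 3.0
    stationary_frames: int = 3
    region_length_um: float = 18.0

    def stage_list(self) -> list[str]:
        req = [s.strip() for s in self.stages.split(",") if s.strip()]
        for s in req:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
        return [s for s in ALL_STAGES if s in req]  # dependency order

    # -- key=value round-trip -------------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# cordflux run configuration (key = value)\n")
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(defaults, key)
            kwargs[key] = type(current)(val)
        return cls(**kwargs)


def _movie_spec(cfg: RunConfig) -> SimMovieSpec:
    rng = np.random.default_rng(cfg.seed + 1)
    vesicles = []
    n_mobile = cfg.n_anterograde + cfg.n_retrograde
    starts = np.linspace(0.1, 0.9, max(n_mobile, 1)) * cfg.cord_length_um
    rng.shuffle(starts)
    for i in range(cfg.n_anterograde):
        vesicles.append(VesicleSpec(float(starts[i]), cfg.speed_um_per_s))
    for i in range(cfg.n_retrograde):
        vesicles.append(VesicleSpec(float(starts[cfg.n_anterograde + i]),
                                    -cfg.speed_um_per_s))
    return SimMovieSpec(
        frames=cfg.frames, frame_rate_hz=cfg.frame_rate_hz,
        cord_length_um=cfg.cord_length_um, vesicles=tuple(vesicles),
        stationary_n=cfg.stationary_n, pixel_size_um=cfg.pixel_size_um,
        punctum_sigma_um=cfg.punctum_sigma_um,
        punctum_amplitude=cfg.punctum_amplitude,
        background_level=cfg.background_level, noise_sd=cfg.noise_sd,
        seed=cfg.seed + 2,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages and return the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.stage_list()
    outputs: dict[str, str] = {}

    def record(name: str, path: Path):
        outputs[name] = str(path.relative_to(out))

    spec = SimImageSpec(
        width_px=cfg.width_px, height_px=cfg.height_px,
        pixel_size_um=cfg.pixel_size_um, n_puncta=cfg.n_puncta,
        punctum_sigma_um=cfg.punctum_sigma_um,
        punctum_amplitude=cfg.punctum_amplitude,
        background_level=cfg.background_level, noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )

    if "simulate" in stages:
        img, truth = make_puncta_image(spec)
        write_tiff_image(out / "puncta.tif", img)
        truth.puncta.to_csv(out / "puncta_truth.csv", index=False)
        record("puncta_image", out / "puncta.tif")
        record("puncta_truth", out / "puncta_truth.csv")

        (ch1, ch2), truth2 = make_two_channel_image(
            spec, cfg.coloc_fraction, cfg.offset_um)
        write_tiff_image(out / "ch1.tif", ch1)
        write_tiff_image(out / "ch2.tif", ch2)
        truth2.puncta.to_csv(out / "two_channel_truth.csv", index=False)
        record("ch1_image", out / "ch1.tif")
        record("ch2_image", out / "ch2.tif")

        gfp_map, _ = make_puncta_image(dataclasses.replace(spec, noise_sd=0.0))
        auto_map = Image(np.full(gfp_map.shape, 0.3 * cfg.punctum_amplitude),
                         pixel_size_um=cfg.pixel_size_um)
        stack, _ = make_lambda_stack(
            gfp_map, auto_map, default_gfp_profile(),
            default_autofluorescence_profile(),
            noise_sd=cfg.lambda_noise_sd, seed=cfg.seed + 3)
        write_tiff_stack(out / "lambda_stack.tif", stack.data)
        record("lambda_stack", out / "lambda_stack.tif")

        movie, mtruth = make_movie(_movie_spec(cfg))
        write_tiff_stack(out / "movie.tif", movie.data)
        mtruth.tracks.to_csv(out / "movie_truth.csv", index=False)
        mtruth.track_classes.to_csv(out / "movie_truth_classes.csv", index=False)
        record("movie", out / "movie.tif")
        record("movie_truth", out / "movie_truth.csv")

    if "puncta" in stages:
        path = out / "puncta.tif"
        if not path.exists():
            raise DependencyError(
                "puncta stage needs an input image: run the 'simulate' stage "
                "first or place puncta.tif in the run directory")
        img = read_tiff_image(path, pixel_size_um=cfg.pixel_size_um)
        mask, thr = auto_threshold(img, method=cfg.threshold_method,
                                   percentile=cfg.threshold_percentile)
        ps = detect_puncta(mask, img, min_area=cfg.min_area,
                           connectivity=cfg.connectivity, threshold=thr,
                           cord_length_um=img.width_um)
        ps.to_csv(out / "puncta_detected.csv")
        record("puncta_detected", out / "puncta_detected.csv")
        with open(out / "puncta_summary.json", "w") as fh:
            json.dump({"n_puncta": len(ps), "threshold": thr,
                       "density_per_100um": puncta_density(ps)}, fh, indent=2)
        record("puncta_summary", out / "puncta_summary.json")

    if "coloc" in stages:
        p1, p2 = out / "ch1.tif", out / "ch2.tif"
        if not (p1.exists() and p2.exists()):
            raise DependencyError(
                "coloc stage needs two-channel images: run 'simulate' first")
        ch1 = read_tiff_image(p1, pixel_size_um=cfg.pixel_size_um)
        ch2 = read_tiff_image(p2, pixel_size_um=cfg.pixel_size_um)
        m1, t1 = auto_threshold(ch1, method="percentile",
                                percentile=cfg.threshold_percentile)
        m2, t2 = auto_threshold(ch2, method="percentile",
                                percentile=cfg.threshold_percentile)
        res = tolerance_coloc(ch1, ch2, m1, m2, tolerance=cfg.coloc_tolerance)
        pr = pearson_coloc(ch1, ch2, m1 | m2)
        write_tiff_image(out / "coloc_mask.tif",
                         Image(res.mask.astype(float), cfg.pixel_size_um))
        with open(out / "coloc_summary.json", "w") as fh:
            json.dump({
                "fraction_ch1_colocalized": res.fraction_ch1_colocalized,
                "n_colocalized_px": res.n_colocalized_px,
                "n_ch1_px": res.n_ch1_px, "tolerance": res.tolerance,
                "pearson_r": pr.r, "pearson_n_px": pr.n_px,
            }, fh, indent=2)
        record("coloc_mask", out / "coloc_mask.tif")
        record("coloc_summary", out / "coloc_summary.json")

    if "unmix" in stages:
        path = out / "lambda_stack.tif"
        if not path.exists():
            raise DependencyError(
                "unmix stage needs a lambda stack: run 'simulate' first")
        stack = LambdaStack(read_tiff_stack(path),
                            wavelengths_nm=np.arange(500, 581, 10),
                            pixel_size_um=cfg.pixel_size_um)
        gfp_ab, auto_ab, resid = unmix(stack, default_gfp_profile(),
                                       default_autofluorescence_profile())
        write_tiff_image(out / "gfp_abundance.tif", gfp_ab)
        write_tiff_image(out / "auto_abundance.tif", auto_ab)
        record("gfp_abundance", out / "gfp_abundance.tif")
        record("auto_abundance", out / "auto_abundance.tif")

    if "kymo" in stages:
        path = out / "movie.tif"
        if not path.exists():
            raise DependencyError(
                "kymo stage needs a movie: run 'simulate' first or place "
                "movie.tif in the run directory")
        movie = TimeLapse(read_tiff_stack(path), frame_rate_hz=cfg.frame_rate_hz,
                          pixel_size_um=cfg.pixel_size_um)
        kymo = build_kymograph(movie)
        detect_thr = cfg.background_level + 0.3 * cfg.punctum_amplitude
        tracks = [classify_track(t, move_px=cfg.move_px,
                                 stationary_frames=cfg.stationary_frames)
                  for t in detect_and_link(kymo, detect_thr)]
        tracks_to_dataframe(tracks).to_csv(out / "tracks.csv", index=False)
        record("tracks", out / "tracks.csv")
        summ = transport_summary(tracks, region_length_um=cfg.region_length_um,
                                 duration_s=movie.duration_s)
        with open(out / "transport_summary.json", "w") as fh:
            json.dump({
                "flux_per_um_per_min": summ.flux_per_um_per_min,
                "n_mobile": summ.n_mobile,
                "n_stationary": summ.n_stationary,
                "n_excluded": summ.n_excluded,
                "frac_anterograde": summ.frac_anterograde,
                "frac_retrograde": summ.frac_retrograde,
                "velocity_mean_sem": summ.velocity_mean_sem,
            }, fh, indent=2)
        record("transport_summary", out / "transport_summary.json")
        write_tiff_image(out / "kymograph.tif",
                         Image(kymo.data, cfg.pixel_size_um))
        record("kymograph", out / "kymograph.tif")

    cfg.to_file(out / "run_config.txt")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "config": {f.name: getattr(cfg, f.name) for f in fields(cfg)},
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
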