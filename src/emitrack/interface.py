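"""Operational shell: file formats, configuration files, chain archives,
run manifests and the command-line interface.

Units are nanometres and seconds everywhere inside the package; unit
conversions happen only here.  CSV is the canonical on-disk track format
(columns ``track_id, frame, t_seconds, x_nm, y_nm, abs_z_nm`` plus
optional CI columns); a minimal TrackMate-flavoured XML dialect
(spots + edges, positions in pixels) is read and written for
interoperability with external tracking tools.  Axial positions are
exported as |z|: the imaging model cannot determine the sign.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import (
    AcquisitionTiming,
    CameraModel,
    Config,
    ConfigError,
    ImageStack,
    ModelConfig,
    Optics,
    RunConfig,
    TrackSet,
    validate_config,
)
from .metrics import localization_resolution, pair_track_sets, tracking_error
from .sampler import Chain, TrackEstimate, map_estimate, run_chain
from .simulator import FIXTURES, make_fixture

__all__ = [
    "read_stack",
    "write_stack",
    "write_tracks",
    "read_tracks_csv",
    "read_trackmate_xml",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "save_chain",
    "load_chain",
    "RunManifest",
    "cli",
]


# --------------------------------------------------------------------------
# image stacks


def read_stack(path, camera: CameraModel, timing: AcquisitionTiming) -> ImageStack:
    """Read a multi-page grayscale TIFF as an image stack.

    Pages map to frames in file order; values pass through unscaled.  Page
    shape must match the camera geometry and the page count the timing.
    """
    values = tifffile.imread(str(path))
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got array of shape {values.shape}")
    if values.shape[1:] != (camera.n_rows, camera.n_cols):
        raise ValueError(
            f"{path}: page shape {values.shape[1:]} does not match camera ({camera.n_rows}, {camera.n_cols})"
        )
    if values.shape[0] != timing.n_frames:
        raise ValueError(f"{path}: {values.shape[0]} pages but timing declares {timing.n_frames} frames")
    return ImageStack(values.astype(float), timing, camera)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(str(path), stack.values.astype(np.float32))


# --------------------------------------------------------------------------
# tracks


def _frame_times(timing: AcquisitionTiming) -> np.ndarray:
    return 0.5 * (timing.t_start + timing.t_end)


def write_tracks(tracks, path, fmt: str = "csv", timing: AcquisitionTiming | None = None, pixel_size: float | None = None):
    """Write a :class:`TrackSet` or :class:`TrackEstimate` to disk.

    ``fmt='csv'`` writes the canonical table (axial column holds |z|; CI
    columns when the estimate carries them).  ``fmt='trackmate-xml'``
    writes the minimal spot/edge structure with positions converted to
    pixel units (``pixel_size`` required).
    """
    est_ci = None
    if isinstance(tracks, TrackEstimate):
        est_ci = tracks.track_ci
        ts = tracks.trackset()
    else:
        ts = tracks
    if fmt == "csv":
        t = _frame_times(timing) if timing is not None else np.arange(ts.n_frames, dtype=float)
        rows = []
        for m in range(ts.n_tracks):
            for n in range(ts.n_frames):
                if not ts.present[m, n]:
                    continue
                x, y, z = ts.positions[m, n]
                row = {
                    "track_id": m,
                    "frame": n + 1,
                    "t_seconds": t[n],
                    "x_nm": x,
                    "y_nm": y,
                    "abs_z_nm": abs(z) if np.isfinite(z) else np.nan,
                }
                if est_ci is not None:
                    for j, c in enumerate(("x", "y", "abs_z")):
                        row[f"{c}_ci_lo_nm"] = est_ci[m, n, j, 0]
                        row[f"{c}_ci_hi_nm"] = est_ci[m, n, j, 1]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "trackmate-xml":
        if pixel_size is None:
            raise ValueError("trackmate-xml export needs pixel_size for nm -> pixel conversion")
        _write_trackmate(ts, path, pixel_size)
    else:
        raise ValueError(f"unknown track format {fmt!r}")


def read_tracks_csv(path) -> TrackSet:
    """Read the canonical CSV back into a TrackSet (z column is |z|)."""
    df = pd.read_csv(path)
    ids = sorted(df["track_id"].unique())
    n_frames = int(df["frame"].max())
    pos = np.full((len(ids), n_frames, 3), np.nan)
    for i, tid in enumerate(ids):
        sub = df[df["track_id"] == tid]
        f = sub["frame"].to_numpy(int) - 1
        pos[i, f, 0] = sub["x_nm"]
        pos[i, f, 1] = sub["y_nm"]
        if "abs_z_nm" in sub:
            pos[i, f, 2] = sub["abs_z_nm"]
    return TrackSet(pos)


def _write_trackmate(ts: TrackSet, path, pixel_size: float) -> None:
    root = ET.Element("TrackMate", version="7")
    model = ET.SubElement(root, "Model", spatialunits="pixel", timeunits="frame")
    allspots = ET.SubElement(model, "AllSpots")
    alltracks = ET.SubElement(model, "AllTracks")
    filtered = ET.SubElement(model, "FilteredTracks")
    spot_id = 0
    track_spots: list[list[tuple[int, int]]] = []
    frames: dict[int, ET.Element] = {}
    for m in range(ts.n_tracks):
        spots = []
        for n in range(ts.n_frames):
            if not ts.present[m, n]:
                continue
            if n not in frames:
                frames[n] = ET.SubElement(allspots, "SpotsInFrame", frame=str(n))
            x, y, z = ts.positions[m, n]
            ET.SubElement(
                frames[n],
                "Spot",
                ID=str(spot_id),
                name=f"ID{spot_id}",
                FRAME=str(n),
                POSITION_T=str(float(n)),
                POSITION_X=str(x / pixel_size),
                POSITION_Y=str(y / pixel_size),
                POSITION_Z=str(abs(z) / pixel_size if np.isfinite(z) else 0.0),
                QUALITY="1.0",
                RADIUS="1.0",
                VISIBILITY="1",
            )
            spots.append((n, spot_id))
            spot_id += 1
        track_spots.append(spots)
    allspots.set("nspots", str(spot_id))
    for m, spots in enumerate(track_spots):
        tr = ET.SubElement(alltracks, "Track", name=f"Track_{m}", TRACK_ID=str(m), NUMBER_SPOTS=str(len(spots)))
        for (n0, s0), (n1, s1) in zip(spots[:-1], spots[1:]):
            ET.SubElement(tr, "Edge", SPOT_SOURCE_ID=str(s0), SPOT_TARGET_ID=str(s1))
        ET.SubElement(filtered, "TrackID", TRACK_ID=str(m))
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")


def read_trackmate_xml(path, pixel_size: float) -> TrackSet:
    """Read a TrackMate-style XML (spots + edges) into a TrackSet, pixels
    converted to nm; tracks are connected components of the edge graph."""
    root = ET.parse(str(path)).getroot()
    model = root.find("Model") if root.find("Model") is not None else root
    spots: dict[int, tuple[int, float, float, float]] = {}
    for sf in model.find("AllSpots") or []:
        for sp in sf:
            sid = int(sp.get("ID"))
            n = int(float(sp.get("FRAME", sf.get("frame", 0))))
            spots[sid] = (
                n,
                float(sp.get("POSITION_X")) * pixel_size,
                float(sp.get("POSITION_Y")) * pixel_size,
                float(sp.get("POSITION_Z", "nan")) * pixel_size,
            )
    tracks_el = model.find("AllTracks")
    track_lists: list[list[int]] = []
    for tr in tracks_el if tracks_el is not None else []:
        members: set[int] = set()
        for e in tr:
            members.add(int(e.get("SPOT_SOURCE_ID")))
            members.add(int(e.get("SPOT_TARGET_ID")))
        if not members:  # single-spot track
            continue
        track_lists.append(sorted(members, key=lambda s: spots[s][0]))
    if not track_lists:
        raise ValueError(f"{path}: no tracks found")
    n_frames = max(s[0] for s in spots.values()) + 1
    pos = np.full((len(track_lists), n_frames, 3), np.nan)
    for i, members in enumerate(track_lists):
        for sid in members:
            n, x, y, z = spots[sid]
            pos[i, n] = (x, y, z)
    return TrackSet(pos)


# --------------------------------------------------------------------------
# configuration files (flat nested-key YAML)

_TIMING_KEYS = ("n_frames", "exposure", "period")


def config_to_dict(config: Config) -> dict:
    cam, opt, tim, mod, run = config.camera, config.optics, config.timing, config.model, config.run
    exposure = float(tim.exposures[0])
    period = float(tim.t_start[1] - tim.t_start[0]) if tim.n_frames > 1 else exposure
    return {
        "camera": {
            "offset": cam.offset,
            "read_variance": cam.read_variance,
            "gain": cam.gain,
            "excess_noise": cam.excess_noise,
            "pixel_size": cam.pixel_size,
            "rows": cam.n_rows,
            "cols": cam.n_cols,
        },
        "optics": {
            "na": opt.numerical_aperture,
            "wavelength": opt.wavelength,
            "sigma0": opt.in_focus_width,
            "dz": opt.axial_scale,
        },
        "timing": {"n_frames": tim.n_frames, "exposure": exposure, "period": period},
        "model": {
            "M": mod.M,
            "K": mod.K,
            "gamma": mod.gamma,
            "z_max": mod.z_max,
            "d_prior_shape": mod.d_prior_shape,
            "d_prior_mean": mod.d_prior_mean,
            "h_prior_shape": mod.h_prior_shape,
            "h_prior_mean": mod.h_prior_mean,
            "f_prior_shape": mod.f_prior_shape,
            "f_prior_mean": mod.f_prior_mean,
            "fixed_brightness": mod.fixed_brightness,
            "constant_background": mod.constant_background,
        },
        "run": {
            "iterations": run.iterations,
            "burn_in": run.burn_in,
            "seed": run.seed,
            "prior_only": run.prior_only,
        },
    }


def config_from_dict(d: dict) -> Config:
    try:
        c = d["camera"]
        camera = CameraModel(
            offset=float(c["offset"]),
            read_variance=float(c["read_variance"]),
            gain=float(c["gain"]),
            excess_noise=float(c["excess_noise"]),
            pixel_size=float(c["pixel_size"]),
            n_rows=int(c["rows"]),
            n_cols=int(c["cols"]),
        )
        o = d["optics"]
        optics = Optics(float(o["na"]), float(o["wavelength"]), float(o["sigma0"]), float(o["dz"]))
        t = d["timing"]
        timing = AcquisitionTiming.regular(int(t["n_frames"]), float(t["exposure"]), float(t.get("period") or t["exposure"]))
    except KeyError as e:
        raise ConfigError(str(e), "missing configuration key") from None
    model = ModelConfig(**{k: v for k, v in d.get("model", {}).items() if v is not None or k in ("z_max", "fixed_brightness")})
    run = RunConfig(**d.get("run", {}))
    return validate_config(camera, optics, timing, model, run)


def load_config(path) -> Config:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# --------------------------------------------------------------------------
# chain archive


def save_chain(chain: Chain, path) -> None:
    """Archive a chain as a single .npz with the configuration embedded;
    :func:`load_chain` restores it, and ``run_chain(..., start=
    chain.state(-1))`` resumes sampling."""
    np.savez_compressed(
        str(path),
        loads=chain.loads,
        tracks=chain.tracks,
        diffusion=chain.diffusion,
        brightness=chain.brightness,
        background=chain.background,
        log_posterior=chain.log_posterior,
        meta=np.frombuffer(
            json.dumps(
                {
                    "config": config_to_dict(chain.config),
                    "seed": chain.seed,
                    "iterations": chain.iterations,
                    "burn_in": chain.burn_in,
                    "acceptance": {k: list(v) for k, v in chain.acceptance.items()},
                }
            ).encode(),
            dtype=np.uint8,
        ),
    )


def load_chain(path) -> Chain:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        return Chain(
            loads=z["loads"],
            tracks=z["tracks"],
            diffusion=z["diffusion"],
            brightness=z["brightness"],
            background=z["background"],
            log_posterior=z["log_posterior"],
            config=config_from_dict(meta["config"]),
            seed=meta["seed"],
            iterations=meta["iterations"],
            burn_in=meta["burn_in"],
            acceptance={k: tuple(v) for k, v in meta["acceptance"].items()},
        )


# --------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run: equal manifests imply
    equal outputs (the seed fixes all randomness)."""

    command: str
    config: dict
    inputs: dict[str, str]  # path -> sha256
    outputs: list[str]
    seed: int
    version: str
    timestamp: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _manifest(command: str, config: Config | None, inputs: list, outputs: list, seed: int) -> RunManifest:
    return RunManifest(
        command=command,
        config=config_to_dict(config) if config else {},
        inputs={str(p): _digest(p) for p in inputs},
        outputs=[str(p) for p in outputs],
        seed=seed,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


# --------------------------------------------------------------------------
# command line

EXIT_CONFIG = 3
EXIT_IO = 4


@click.group()
@click.version_option(__version__)
def cli():
    """Joint Bayesian emitter counting and superresolved tracking."""


@cli.command()
@click.argument("fixture", type=click.Choice(sorted(FIXTURES)))
@click.option("--out", "-o", type=click.Path(), default=".", help="Output directory.")
@click.option("--seed", type=int, default=None, help="Override the fixture's fixed seed.")
def simulate(fixture, out, seed):
    """Simulate a named benchmark scenario to TIFF plus ground-truth tracks."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, truth, scenario = make_fixture(fixture, seed=seed)
    tiff = outdir / f"{fixture}.tif"
    write_stack(stack, tiff)
    cfg = scenario.config()
    save_config(cfg, outdir / f"{fixture}.config.yaml")
    outputs = [tiff, outdir / f"{fixture}.config.yaml"]
    if truth is not None:
        csv = outdir / f"{fixture}.truth.csv"
        xml = outdir / f"{fixture}.truth.xml"
        write_tracks(truth, csv, "csv", timing=scenario.timing)
        write_tracks(truth, xml, "trackmate-xml", pixel_size=scenario.camera.pixel_size)
        outputs += [csv, xml]
    _manifest("simulate", cfg, [], outputs, scenario.seed if seed is None else seed).write(outdir / f"{fixture}.manifest.json")
    click.echo(f"wrote {', '.join(str(o) for o in outputs)}")


@cli.command()
@click.argument("tiff", type=click.Path(exists=True))
@click.option("--config", "-c", "config_path", type=click.Path(exists=True), required=True)
@click.option("--out", "-o", type=click.Path(), default=".", help="Output directory.")
@click.option("--seed", type=int, default=None, help="Override the configured seed.")
def track(tiff, config_path, out, seed):
    """Infer emitter number and tracks from a TIFF stack."""
    try:
        config = load_config(config_path)
    except (ConfigError, yaml.YAMLError) as e:
        raise SystemExit(EXIT_CONFIG) from e
    if seed is not None:
        config = config.with_run(seed=seed)
    try:
        stack = read_stack(tiff, config.camera, config.timing)
    except (OSError, ValueError) as e:
        click.echo(f"error reading {tiff}: {e}", err=True)
        raise SystemExit(EXIT_IO) from e
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    click.echo(f"running {config.run.iterations} sweeps (burn-in {config.run.effective_burn_in})...")
    chain = run_chain(stack, config)
    est = map_estimate(chain)
    rates = ", ".join(f"{k}={v:.2f}" for k, v in chain.acceptance_rates().items())
    click.echo(f"acceptance rates: {rates}")
    click.echo(f"MAP emitter count B = {est.n_emitters}; count posterior {est.count_posterior}")
    stem = Path(tiff).stem
    chain_path = outdir / f"{stem}.chain.npz"
    map_csv = outdir / f"{stem}.map_tracks.csv"
    map_xml = outdir / f"{stem}.map_tracks.xml"
    post_json = outdir / f"{stem}.posterior.json"
    save_chain(chain, chain_path)
    write_tracks(est, map_csv, "csv", timing=config.timing)
    write_tracks(est, map_xml, "trackmate-xml", pixel_size=config.camera.pixel_size)
    with open(post_json, "w") as fh:
        json.dump(
            {
                "map_count": est.n_emitters,
                "count_posterior": est.count_posterior,
                "map_diffusion_nm2_per_s": est.diffusion,
                "diffusion_ci_nm2_per_s": est.diffusion_ci,
                "map_log_posterior": est.log_posterior,
            },
            fh,
            indent=2,
        )
    _manifest("track", config, [tiff, config_path], [chain_path, map_csv, map_xml, post_json], config.run.seed).write(
        outdir / f"{stem}.manifest.json"
    )
    click.echo(f"wrote {chain_path}, {map_csv}, {map_xml}, {post_json}")


@cli.command()
@click.argument("estimated", type=click.Path(exists=True))
@click.argument("reference", type=click.Path(exists=True))
@click.option("--gate-px", type=float, default=5.0, help="Gate in pixels ('inf' via --gate-nm).")
@click.option("--gate-nm", type=float, default=None, help="Gate in nm (overrides --gate-px; inf allowed).")
@click.option("--pixel-size", type=float, default=133.0, help="nm per pixel (for the gate and XML input).")
@click.option("--out", "-o", type=click.Path(), default=None, help="Write the report as JSON.")
def evaluate(estimated, reference, gate_px, gate_nm, pixel_size, out):
    """Score an estimated track file against a reference track file."""

    def read_any(path):
        return read_trackmate_xml(path, pixel_size) if str(path).endswith(".xml") else read_tracks_csv(path)

    try:
        est, ref = read_any(estimated), read_any(reference)
    except (OSError, ValueError) as e:
        click.echo(f"error reading tracks: {e}", err=True)
        raise SystemExit(EXIT_IO) from e
    gate = gate_nm if gate_nm is not None else gate_px * pixel_size
    pairing = pair_track_sets(est, ref, gate)
    err = tracking_error(est, ref, gate)
    report = {
        "gate_nm": gate,
        "pairing_distance_nm": pairing.total,
        "n_pairs": len(pairing.pairs),
        "unmatched_estimated": list(pairing.unmatched_1),
        "unmatched_reference": list(pairing.unmatched_2),
        "tracking_error_nm": err,
    }
    try:
        report["localization_resolution_nm"] = localization_resolution(est, ref)
    except ValueError as e:
        report["localization_resolution_nm"] = None
        report["localization_resolution_note"] = str(e)
    click.echo(json.dumps(report, indent=2))
    if out:
        with open(out, "w") as fh:
            json.dump(report, fh, indent=2)


if __name__ == "__main__":  # pragma: no cover
    sys.exit(cli())
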