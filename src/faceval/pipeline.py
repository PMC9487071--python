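"""End-to-end validation run: simulate/load, register, deviate, measure.

A run is driven by a :class:`RunConfig` holding either real input paths
or a synthetic specification (never both).  All randomness flows from
the single config seed, and reports are written with sorted keys and
shortest round-trip floats, so identical configs give byte-identical
output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

from . import deviation as dev
from . import measurements as meas
from . import mesh_io, registration, synthetic_face
from .errors import FacevalError, ValidationError

log = logging.getLogger(__name__)

#: landmarks whose deviations the report tabulates
REPORT_LANDMARKS = ("Prn", "Ls", "Li", "Lch", "Rch", "Pg'", "Gn'", "Me'")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    synthetic: dict | None = None
    test_mesh: str | None = None
    reference_mesh: str | None = None
    test_landmarks: str | None = None
    reference_landmarks: str | None = None
    icp: registration.IcpParams = field(default_factory=registration.IcpParams)
    regions: tuple = ("facial", "perioral")
    color_limit: float = 2.0

    def __post_init__(self):
        real = [self.test_mesh, self.reference_mesh,
                self.test_landmarks, self.reference_landmarks]
        has_real = any(p is not None for p in real)
        if has_real and self.synthetic is not None:
            raise ValidationError(
                "config must provide real inputs or a synthetic spec, not both")
        if not has_real and self.synthetic is None:
            raise ValidationError(
                "config must provide real inputs or a synthetic spec")
        if has_real and not all(p is not None for p in real):
            raise ValidationError("all four real input paths are required")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        icp = registration.IcpParams(**doc.pop("icp", {}))
        regions = tuple(doc.pop("regions", ("facial", "perioral")))
        return cls(icp=icp, regions=regions, **doc)


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _synthetic_pair(cfg: RunConfig, out_dir):
    spec_kw = dict(cfg.synthetic.get("face", {}))
    spec_kw.setdefault("seed", cfg.seed)
    face_spec = synthetic_face.SyntheticFaceSpec(**spec_kw)
    reference, ref_lms = synthetic_face.generate_face(face_spec)

    deform_kw = cfg.synthetic.get("deformation", {})
    if deform_kw.get("kind", "study_like") == "study_like":
        deform = synthetic_face.study_like_deformation(
            face_spec, seed=cfg.seed,
            noise_sd=deform_kw.get("noise_sd", 0.05))
    else:
        deform = synthetic_face.DeformationSpec(
            bumps=tuple(synthetic_face.Bump(**b)
                        for b in deform_kw.get("bumps", ())),
            rotvec_deg=tuple(deform_kw.get("rotvec_deg", (0, 0, 0))),
            translation=tuple(deform_kw.get("translation", (0, 0, 0))),
            noise_sd=deform_kw.get("noise_sd", 0.0),
            seed=cfg.seed)
    test, test_lms, truth = synthetic_face.apply_deformation(
        reference, ref_lms, deform)

    mesh_io.write_obj(reference, out_dir / "reference.obj")
    mesh_io.write_obj(test, out_dir / "test.obj")
    mesh_io.write_landmarks(ref_lms, out_dir / "reference.landmarks.json")
    mesh_io.write_landmarks(test_lms, out_dir / "test.landmarks.json")
    with open(out_dir / "truth.csv", "w") as fh:
        fh.write("vertex,displacement_mm\n")
        for i, d in enumerate(truth):
            fh.write(f"{i},{d:.17g}\n")
    return test, reference, test_lms, ref_lms


def run_validation(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``."""
    from pathlib import Path

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_times = {}

    def staged(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kw)
        except FacevalError as e:
            raise type(e)(f"[stage {name}] {e}") from e
        stage_times[name] = time.perf_counter() - t0
        log.info("stage %s: %.3f s", name, stage_times[name])
        return result

    if cfg.synthetic is not None:
        test, reference, test_lms, ref_lms = staged(
            "simulate", _synthetic_pair, cfg, out_dir)
    else:
        def load():
            return (mesh_io.read_obj(cfg.test_mesh),
                    mesh_io.read_obj(cfg.reference_mesh),
                    mesh_io.read_landmarks(cfg.test_landmarks),
                    mesh_io.read_landmarks(cfg.reference_landmarks))
        test, reference, test_lms, ref_lms = staged("load", load)

    reg = staged("register", registration.two_step_register,
                 test, reference, test_lms, ref_lms, cfg.icp)
    _json_dump(reg.transform.to_dict(), out_dir / "transform.json")

    registered = mesh_io.TriangleMesh(
        reg.transform.apply(test.vertices), test.faces.copy())
    registered_lms = test_lms.transformed(reg.transform.apply)

    frame = staged("frame", dev.build_facial_frame, ref_lms)

    region_reports = {}
    colormap_done = False
    for region in cfg.regions:
        def analyze(region=region):
            cropped = dev.crop_region(registered, ref_lms, frame, region)
            field_ = dev.deviation_field(cropped, reference, region)
            return cropped, field_, dev.rmse(field_)
        cropped, field_, summary = staged(f"deviate[{region}]", analyze)
        region_reports[region] = {
            "rmse_mm": summary.rmse, "mean_mm": summary.mean,
            "sd_mm": summary.sd, "n": summary.n,
        }
        if not colormap_done:
            colored = dev.colorize(field_, cropped, cfg.color_limit)
            mesh_io.write_ply_colored(colored, out_dir / "colormap.ply")
            colormap_done = True

    lm_names = [n for n in REPORT_LANDMARKS
                if n in registered_lms and n in ref_lms]
    lm_dev = staged("landmarks", dev.landmark_deviation,
                    registered_lms, ref_lms, frame, lm_names)

    ref_meas = staged("measure[reference]", meas.measure_all, ref_lms)
    test_meas = staged("measure[test]", meas.measure_all, registered_lms)
    differences = {k: ref_meas[k] - test_meas[k] for k in ref_meas}

    report = {
        "seed": cfg.seed,
        "parameters": {
            "icp": {
                "min_iterations": cfg.icp.min_iterations,
                "max_iterations": cfg.icp.max_iterations,
                "threshold_mm": cfg.icp.threshold,
                "tolerance_mm": cfg.icp.tolerance,
                "sampling_fraction": cfg.icp.sampling_fraction,
            },
            "color_limit_mm": cfg.color_limit,
        },
        "registration": {
            "landmark_rms_mm": reg.landmark_rms,
            "surface_rms_mm": reg.surface_rms,
            "iterations": reg.icp.iterations,
        },
        "regions": region_reports,
        "landmarks": {
            name: {"d": d.d, "dx": d.dx, "dy": d.dy, "dz": d.dz}
            for name, d in lm_dev.items()
        },
        "measurements": {
            "reference": ref_meas,
            "test": test_meas,
            "difference": differences,
        },
    }
    _json_dump(report, out_dir / "report.json")

    from . import __version__
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"faceval {__version__}\nseed {cfg.seed}\n")
        for name, dt in stage_times.items():
            fh.write(f"stage {name}: {dt:.3f} s\n")
    return report
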