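"""End-to-end pipeline: synthesize -> split -> inflate -> analyze.

Glues the stages together for one aneurysm and writes a run directory with
the meshes, the thickness field and a JSON report carrying I_S, sac volume,
I_BA, I_delta and the detected extreme points.  Fully reproducible from the
config (the geometry stages are deterministic; the seed covers synthesis).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as awio
from .analysis import (compute_Idelta, compute_IS, extract_isolines,
                       find_extreme_points, aneurysm_volume, isoline_regularity)
from .inflation import InflationConfig, inflate_to_mold, thickness_summary
from .mesh import TriangleMesh, cap_all_ports, surface_area
from .neck import split_at_neck
from .synthetic import AneurysmSpec, ModelPair, make_model_pair

log = logging.getLogger("aneuwall")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One pipeline run.

    Either ``spec`` (synthetic geometry) or ``model_a_path`` + ``neck_path``
    (external STL plus neck polyline JSON) must be given.  ``n_levels`` and
    ``k_levels`` control the isoline analysis.
    """

    out_dir: Path
    spec: Optional[AneurysmSpec] = None
    model_a_path: Optional[Path] = None
    model_b_path: Optional[Path] = None
    neck_path: Optional[Path] = None
    inflation: InflationConfig = field(default_factory=InflationConfig)
    n_levels: int = 200
    k_levels: int = 8
    seed: int = 20200101

    def config_hash(self) -> str:
        payload = json.dumps({
            "spec": None if self.spec is None else vars(self.spec) | {
                "bleb": None if self.spec.bleb is None else vars(self.spec.bleb),
                "dome_axes": list(self.spec.dome_axes),
            },
            "model_a": str(self.model_a_path), "model_b": str(self.model_b_path),
            "neck": str(self.neck_path),
            "inflation": vars(self.inflation),
            "n_levels": self.n_levels, "k_levels": self.k_levels,
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_neck(path: Path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    return np.asarray(data["polyline"] if isinstance(data, dict) else data,
                      dtype=float)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start, config hash %s", config.config_hash())

    stage = "synthesize"
    try:
        if config.spec is not None:
            pair = make_model_pair(config.spec)
        else:
            if config.model_a_path is None or config.neck_path is None:
                raise ValueError("need either a synthetic spec or model A + neck")
            model_a = awio.read_mesh(config.model_a_path)
            neck = _load_neck(config.neck_path)
            model_b = (awio.read_mesh(config.model_b_path)
                       if config.model_b_path else None)
            pair = ModelPair(model_a=model_a, model_b=model_b, neck_curve=neck)
        awio.write_stl(pair.model_a, out / "A.stl")
        if pair.model_b is not None:
            awio.write_stl(pair.model_b, out / "B.stl")

        stage = "split"
        sac, _parent_a = split_at_neck(pair.model_a, pair.neck_curve)
        if pair.model_b is not None:
            patch, _parent_b = split_at_neck(pair.model_b, pair.neck_curve)
        else:
            from .neck import neck_split
            patch = neck_split(pair.model_a, pair.neck_curve).patch_mesh
        awio.write_stl(sac, out / "sac.stl")
        awio.write_stl(patch, out / "patch.stl")
        s_a = surface_area(sac)
        s_b = surface_area(patch)

        stage = "volume"
        volume = None
        if pair.model_b is not None:
            volume = aneurysm_volume(cap_all_ports(pair.model_a),
                                     cap_all_ports(pair.model_b))

        stage = "inflate"
        result = inflate_to_mold(patch, sac, config.inflation)
        awio.write_stl(result.inflated_mesh, out / "inflated.stl")
        awio.write_thickness_csv(result.inflated_mesh, result.stretch,
                                 result.thickness, out / "thickness.csv")
        delta_prime, delta_bar, i_ba = thickness_summary(result)

        stage = "analyze"
        i_s = compute_IS(s_a, s_b)
        i_delta = compute_Idelta(i_ba, i_s)
        extremes = find_extreme_points(result.thickness, result.inflated_mesh)
        isolines = extract_isolines(result.thickness, result.inflated_mesh,
                                    n_levels=config.n_levels)
        global_min = next(p for p in extremes if p.is_global_min)
        try:
            regularity = isoline_regularity(result.thickness, result.inflated_mesh,
                                            global_min, config.k_levels,
                                            n_levels=config.n_levels)
        except ValueError as exc:
            log.warning("isoline regularity unavailable: %s", exc)
            regularity = None

        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "S_A_mm2": s_a,
            "S_B_mm2": s_b,
            "volume_mm3": volume,
            "I_S": i_s,
            "I_BA": i_ba,
            "I_delta": i_delta,
            "delta_b": result.delta_b,
            "delta_b_prime": delta_prime,
            "delta_bar": delta_bar,
            "converged": result.converged,
            "iterations": result.iterations,
            "n_isoline_levels": len(isolines.levels),
            "isoline_regularity_cv": regularity,
            "extreme_points": [
                {"vertex": p.vertex, "position": list(map(float, p.position)),
                 "thickness": p.thickness, "is_global_min": p.is_global_min}
                for p in sorted(extremes, key=lambda p: p.thickness)
            ],
            "truth": pair.truth,
        }
        awio.write_report(report, out / "report.json")
        log.info("pipeline done: I_S=%.4f I_BA=%.4f I_delta=%.4f", i_s, i_ba, i_delta)
        return out
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        (out / "failed_stage.txt").write_text(stage + "\n")
        raise
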