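"""Scene configuration: schema-validated YAML → simulator objects.

A scene file describes the virtual specimen, its dyes, the light sheet, the
camera, marching quadrature, the emission filter and the spectral grid.  The
schema is enforced by pydantic before any rendering starts, and a SHA-256
hash of the canonical config is recorded in every output sidecar for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .acquisition import OrthographicThinLensCamera
from .fluorophores import load_fluorophore, load_fluorophore_file
from .illumination import LightSheet
from .integrator import MarchSettings, Scene
from .specimen import (
    FluorophoreTable,
    load_grid,
    make_homogeneous_cube,
    make_synthetic_neurons,
)
from .spectral import EmissionFilter, WavelengthGrid
from .validation import make_axial_rod_phantom

__all__ = ["SceneConfig", "load_config", "build_scene", "config_hash"]


class SpectralConfig(BaseModel):
    model_config = {"extra": "forbid"}
    start_nm: float = 300.0
    stop_nm: float = 800.0
    step_nm: float = 5.0


class SpecimenConfig(BaseModel):
    model_config = {"extra": "forbid"}
    type: Literal["cube", "neurons", "rods", "grid"]
    # cube
    side_um: float = 2.0
    density_cm3: float = 1.0e18
    # neurons / rods
    n_cells: int = 5
    n_rods: int = 12
    box_um: float = 60.0
    z_extent_um: float = 30.0
    rod_radius_um: float = 1.5
    phantom_seed: int = 7
    # grid import
    grid_prefix: Optional[str] = None
    # shared
    voxel_size_um: float = 0.1
    sigma_s_elastic_cm: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.type == "grid" and not self.grid_prefix:
            raise ValueError("specimen.type 'grid' requires grid_prefix")
        return self


class FluorophoreRef(BaseModel):
    model_config = {"extra": "forbid"}
    name: Optional[str] = None  # bundled name
    file: Optional[str] = None  # YAML definition file

    @model_validator(mode="after")
    def _check(self):
        if bool(self.name) == bool(self.file):
            raise ValueError("give exactly one of fluorophore name or file")
        return self


class SheetConfig(BaseModel):
    model_config = {"extra": "forbid"}
    thickness_um: float = 5.0
    height_um: float = 100.0
    lambda_ex_nm: float = 488.0
    photons: float = 1.0e12
    z_um: float = 0.0
    attenuate: bool = False


class CameraConfig(BaseModel):
    model_config = {"extra": "forbid"}
    film_width_um: float = 100.0
    film_height_um: float = 100.0
    resolution: tuple[int, int] = (128, 128)
    aperture_radius_um: float = 0.0
    focus_distance_um: float = 1000.0
    samples_per_pixel: int = 8
    center_um: tuple[float, float] = (0.0, 0.0)
    view_sign: int = -1


class MarchingConfig(BaseModel):
    model_config = {"extra": "forbid"}
    step_um: Optional[float] = None  # default: voxel_size / 2
    jitter: bool = False


class FilterConfig(BaseModel):
    model_config = {"extra": "forbid"}
    type: Literal["none", "unity", "notch", "bandpass"] = "notch"
    lo_nm: float = 500.0
    hi_nm: float = 550.0


class SceneConfig(BaseModel):
    model_config = {"extra": "forbid"}
    seed: int = 0
    specimen: SpecimenConfig
    fluorophores: list[FluorophoreRef] = Field(default_factory=lambda: [FluorophoreRef(name="gfp")])
    sheet: SheetConfig = SheetConfig()
    camera: CameraConfig = CameraConfig()
    marching: MarchingConfig = MarchingConfig()
    filter: FilterConfig = FilterConfig()
    spectral: SpectralConfig = SpectralConfig()
    output_dir: str = "out"


def load_config(path) -> SceneConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    # allow bare-string fluorophore entries
    if isinstance(doc.get("fluorophores"), list):
        doc["fluorophores"] = [
            {"name": f} if isinstance(f, str) else f for f in doc["fluorophores"]
        ]
    return SceneConfig.model_validate(doc)


def config_hash(cfg: SceneConfig) -> str:
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_scene(cfg: SceneConfig, base_dir: Path | None = None):
    """Instantiate (scene, camera, emission_filter) from a validated config."""
    base_dir = Path(base_dir or ".")
    sg = WavelengthGrid(
        cfg.spectral.start_nm, cfg.spectral.stop_nm, cfg.spectral.step_nm
    )
    sp = cfg.specimen
    if sp.type == "cube":
        grid = make_homogeneous_cube(
            sp.side_um, sp.density_cm3, 0, sp.voxel_size_um, sp.sigma_s_elastic_cm
        )
    elif sp.type == "neurons":
        half = sp.box_um / 2.0
        grid = make_synthetic_neurons(
            sp.n_cells,
            sp.phantom_seed,
            (-half, -half, -half),
            (half, half, half),
            density=sp.density_cm3,
            voxel_size_um=sp.voxel_size_um,
            sigma_s_elastic_cm=sp.sigma_s_elastic_cm,
        )
    elif sp.type == "rods":
        grid = make_axial_rod_phantom(
            sp.n_rods,
            sp.phantom_seed,
            sp.box_um,
            sp.z_extent_um,
            sp.rod_radius_um,
            sp.density_cm3,
            sp.voxel_size_um,
        )
    else:
        grid = load_grid(base_dir / sp.grid_prefix)

    fluos = FluorophoreTable(
        [
            load_fluorophore(ref.name, sg)
            if ref.name
            else load_fluorophore_file(base_dir / ref.file, sg)
            for ref in cfg.fluorophores
        ]
    )
    sheet = LightSheet(
        thickness_um=cfg.sheet.thickness_um,
        height_um=cfg.sheet.height_um,
        lambda_ex_nm=cfg.sheet.lambda_ex_nm,
        photons=cfg.sheet.photons,
        z_um=cfg.sheet.z_um,
        attenuate=cfg.sheet.attenuate,
    )
    step = cfg.marching.step_um or grid.voxel_size_um / 2.0
    march = MarchSettings(step_um=step, jitter=cfg.marching.jitter, seed=cfg.seed)
    scene = Scene(grid, sheet, fluos, march, sg)
    camera = OrthographicThinLensCamera(
        film_width_um=cfg.camera.film_width_um,
        film_height_um=cfg.camera.film_height_um,
        resolution=tuple(cfg.camera.resolution),
        aperture_radius_um=cfg.camera.aperture_radius_um,
        focus_distance_um=cfg.camera.focus_distance_um,
        view_sign=cfg.camera.view_sign,
        samples_per_pixel=cfg.camera.samples_per_pixel,
        center_um=tuple(cfg.camera.center_um),
        seed=cfg.seed,
    )
    if cfg.filter.type in ("none", "unity"):
        emission_filter = None if cfg.filter.type == "none" else EmissionFilter.unity(sg)
    elif cfg.filter.type == "notch":
        emission_filter = EmissionFilter.notch(sg, cfg.sheet.lambda_ex_nm)
    else:
        emission_filter = EmissionFilter.bandpass(sg, cfg.filter.lo_nm, cfg.filter.hi_nm)
    return scene, camera, emission_filter
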