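"""Study configuration: which bones, muscles, joints and landmarks make up
an analysis, plus the numeric constants of the recording setup.

The configuration is a single declarative YAML mapping. Every numeric
default (filter cutoffs, frame rates, alpha, baseline window) can be
overridden per study. Defaults reflect a typical biplanar X-ray suction
feeding setup: 300 frames/s video, 1000 Hz pressure, 40 Hz kinematic and
300 Hz pressure low-pass cutoffs, alpha radius 2 (scene units), bilateral
endocast doubling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml


@dataclass
class BoneSpec:
    """A marked bone: its tracked-marker names (reference coordinates live in
    the reference-geometry CSV)."""
    name: str
    markers: list[str]


@dataclass
class MuscleChain:
    """An axial muscle instrumented with an ordered chain of intramuscular
    markers; adjacent pairs are subregions, first-to-last the whole region."""
    name: str
    markers: list[str]
    mass_kg: float | None = None

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError(f"muscle {self.name!r} needs >=2 markers")


@dataclass
class FiberMuscle:
    """A cranial muscle measured from bone-attached fiber landmarks: three
    (origin, insertion) landmark-name pairs. For muscles with substantial
    tendons the measured length is the muscle-tendon unit, not the fiber."""
    name: str
    fibers: list[tuple[str, str]]
    mass_kg: float | None = None
    muscle_tendon_unit: bool = False

    def __post_init__(self) -> None:
        if len(self.fibers) != 3:
            raise ValueError(f"fiber muscle {self.name!r} needs exactly 3 fiber pairs")


@dataclass
class JointDef:
    """A joint coordinate system: one anatomical coordinate system placed at
    the joint (origin and axes in world/scene coordinates at the setup
    frame) and duplicated onto the proximal body (usually the body plane)
    and the distal mobile bone, so the two copies coincide at setup."""
    name: str
    proximal: str
    distal: str
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def axes_matrix(self) -> np.ndarray:
        m = np.asarray(self.axes, float)
        if m.shape != (3, 3):
            raise ValueError(f"joint {self.name!r}: axes must be 3x3")
        return m


@dataclass
class EndocastSettings:
    landmarks: list[str]
    alpha: float = 2.0
    bilateral_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.bilateral_factor <= 0:
            raise ValueError("bilateral_factor must be positive")


@dataclass
class FilterSettings:
    """Zero-phase Butterworth low-pass cutoffs; ``None`` disables a filter."""
    cutoff_kinematics_hz: float | None = 40.0
    cutoff_pressure_hz: float | None = 300.0


@dataclass
class StudyConfig:
    bones: list[BoneSpec] = field(default_factory=list)
    body_plane_markers: list[str] = field(default_factory=list)
    muscles: list[MuscleChain] = field(default_factory=list)
    fiber_muscles: list[FiberMuscle] = field(default_factory=list)
    joints: list[JointDef] = field(default_factory=list)
    endocast: EndocastSettings | None = None
    filters: FilterSettings = field(default_factory=FilterSettings)
    # gape landmarks: (upper jaw tip, lower jaw tip)
    gape_landmarks: tuple[str, str] | None = None
    masses_kg: dict = field(default_factory=dict)
    body_mass_kg: float | None = None
    pressure_calibration_pa_per_mv: float | None = None
    frame_rate_hz: float = 300.0
    pressure_rate_hz: float = 1000.0
    baseline_window_s: float = 0.1
    baseline_end_before_peak_s: float = 0.2
    units: str = "cm"
    individual: str = "ind1"
    # path (relative to the config file) of the reference-geometry CSV
    reference_geometry: str | None = None

    def validate(self) -> None:
        if self.frame_rate_hz <= 0 or self.pressure_rate_hz <= 0:
            raise ValueError("frame rates must be positive")
        if len(self.body_plane_markers) not in (0,) and len(self.body_plane_markers) < 3:
            raise ValueError("body plane needs >=3 markers")
        for name, m in self.masses_kg.items():
            if m <= 0:
                raise ValueError(f"mass {name!r} must be positive")
        if self.body_mass_kg is not None and self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gape_landmarks"] = list(self.gape_landmarks) if self.gape_landmarks else None
        for j in d["joints"]:
            j["origin"] = [float(x) for x in j["origin"]]
            j["axes"] = [[float(x) for x in row] for row in j["axes"]]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["bones"] = [BoneSpec(**b) for b in d.get("bones", [])]
        d["muscles"] = [MuscleChain(**m) for m in d.get("muscles", [])]
        d["fiber_muscles"] = [
            FiberMuscle(name=f["name"],
                        fibers=[tuple(p) for p in f["fibers"]],
                        mass_kg=f.get("mass_kg"),
                        muscle_tendon_unit=f.get("muscle_tendon_unit", False))
            for f in d.get("fiber_muscles", [])
        ]
        d["joints"] = [
            JointDef(name=j["name"], proximal=j["proximal"], distal=j["distal"],
                     origin=tuple(j.get("origin", (0, 0, 0))),
                     axes=tuple(tuple(r) for r in j.get("axes",
                               ((1, 0, 0), (0, 1, 0), (0, 0, 1)))))
            for j in d.get("joints", [])
        ]
        if d.get("endocast"):
            d["endocast"] = EndocastSettings(**d["endocast"])
        if d.get("filters"):
            d["filters"] = FilterSettings(**d["filters"])
        if d.get("gape_landmarks"):
            d["gape_landmarks"] = tuple(d["gape_landmarks"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
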