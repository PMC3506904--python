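"""Digital phantoms and simulated dual-isotope studies.

A simplified parametric torso stands in for a NURBS-based cardiac-torso
phantom: body ellipsoid, two lung ellipsoids, a liver ellipsoid, a spine
cylinder (bone) and a half-ellipsoid myocardial shell with a ventricular
cavity.  Perfusion defects are angular sectors of the shell defined in
short-axis polar coordinates.  A cylindrical water phantom with the same
cardiac insert emulates a physical Jaszczak-style acquisition.

``simulate_study`` produces complete dual-isotope projection data: analytic
primaries plus Monte-Carlo self-scatter per window, Tc-99m down-scatter
added to the Tl-201 window, each window scaled to its target total counts
before Poisson sampling.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .containers import ActivityVolume, AttenuationMap, ProjectionSet
from .physics import (TC99M, TL201, TC_WINDOW, TL_WINDOW, EnergyWindow,
                      MaterialTable, default_material_table, window_acceptance)
from .projector import CollimatorModel, Geometry, SpectSystem

__all__ = [
    "DefectSpec",
    "PhantomSpec",
    "StudySpec",
    "CardiacPhantom",
    "SimulatedStudy",
    "ORGAN_IDS",
    "cardiac_phantom_spec",
    "jaszczak_phantom_spec",
    "build_cardiac_phantom",
    "build_jaszczak_phantom",
    "simulate_study",
    "add_poisson_noise",
    "collapse_projections",
]

# organ label ids in the organ grid
ORGAN_IDS = {
    "outside": 0,
    "background": 1,
    "lung": 2,
    "liver": 3,
    "myocardium": 4,
    "ventricle": 5,
    "bone": 6,
}

# material label ids in the attenuation map
_MATERIALS = ("", "soft_tissue", "lung", "bone")
_AIR, _SOFT, _LUNG, _BONE = range(4)

_SECTOR_ANGLES = {"lateral": 0.0, "anterior": 90.0, "septal": 180.0,
                  "inferior": 270.0}


@dataclass(frozen=True)
class DefectSpec:
    """Perfusion defect: an angular sector of the myocardial shell.

    ``fraction`` is the residual activity as a fraction of the myocardial
    concentration; ``isotopes`` states which activity volume carries the
    defect ("tl", "tc" or "both" — a reversible defect is present in the
    stress Tl-201 volume only).
    """

    sector: str
    fraction: float
    extent_deg: float = 60.0
    axial_mm: float = 20.0
    axial_center_mm: float = 0.0  # relative to the heart centre
    isotopes: str = "both"

    def __post_init__(self) -> None:
        if self.sector not in _SECTOR_ANGLES:
            raise ValueError(f"unknown wall sector {self.sector!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("defect fraction must lie in [0, 1]")
        if self.extent_deg <= 0 or self.axial_mm <= 0:
            raise ValueError("defect extent must be positive")
        if self.isotopes not in ("tl", "tc", "both"):
            raise ValueError("isotopes must be 'tl', 'tc' or 'both'")


# Versioned default torso geometry (mm).  Chosen so that organ regions are
# pairwise disjoint on the default grid; the builder verifies this.
DEFAULT_TORSO_GEOMETRY = {
    "body": {"center": (0.0, 0.0, 0.0), "semi": (165.0, 105.0, 200.0)},
    "lung_left": {"center": (92.0, -30.0, 55.0), "semi": (32.0, 42.0, 82.0)},
    "lung_right": {"center": (-92.0, -30.0, 55.0), "semi": (32.0, 42.0, 82.0)},
    "liver": {"center": (-55.0, 10.0, -80.0), "semi": (70.0, 60.0, 50.0)},
    "spine": {"center": (0.0, -85.0), "radius": 14.0},
    "heart": {"center": (45.0, 40.0, 50.0), "outer_semi": (33.0, 33.0, 45.0),
              "wall_mm": 12.0, "base_frac": 0.5},
}

DEFAULT_JASZCZAK_GEOMETRY = {
    "cylinder": {"radius": 108.0, "half_height": 93.0},
    "heart": {"center": (0.0, 30.0, 0.0), "outer_semi": (30.0, 30.0, 40.0),
              "wall_mm": 10.0, "base_frac": 0.5},
}


@dataclass
class PhantomSpec:
    """Everything needed to voxelise one phantom configuration.

    ``activities`` maps isotope key ("tc"/"tl") to per-organ values: relative
    concentrations per voxel when ``activity_mode == "per_voxel"``, or total
    compartment activities (MBq) when ``activity_mode == "total"`` (defect
    totals then come from ``defect_<sector>`` entries).
    """

    grid: tuple = (64, 64, 64)
    voxel_mm: float = 6.6
    geometry: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_TORSO_GEOMETRY))
    activities: dict = field(default_factory=dict)
    defects: tuple = ()
    activity_mode: str = "per_voxel"

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.activity_mode not in ("per_voxel", "total"):
            raise ValueError("activity_mode must be 'per_voxel' or 'total'")
        heart = self.geometry.get("heart", {})
        if heart and heart.get("wall_mm", 1.0) <= 0:
            raise ValueError("myocardial wall thickness must be positive")
        for iso, per_organ in self.activities.items():
            for organ, val in per_organ.items():
                if val < 0:
                    raise ValueError(f"negative activity for {iso}/{organ}")
        self.defects = tuple(self.defects)


# Table-1-style per-voxel activity configurations.  Keys are phantom ids;
# all four share the Tl-201 activities, the Tc-99m side differs, and the
# defect lists encode reversibility (a defect present in the Tl volume only
# is reversible).
_TL_ACT = {"myocardium": 50.0, "ventricle": 3.0, "lung": 2.0, "liver": 3.0,
           "background": 3.0}
_TC_ACT_A = {"myocardium": 180.0, "ventricle": 6.0, "lung": 18.0,
             "liver": 90.0, "background": 6.0}
_TC_ACT_B = {"myocardium": 95.0, "ventricle": 3.0, "lung": 9.0,
             "liver": 189.0, "background": 3.0}

CARDIAC_CONFIGS = {
    1: {"tc": _TC_ACT_A,
        "defects": [DefectSpec("anterior", 0.2, isotopes="both"),
                    DefectSpec("septal", 0.4, isotopes="both")]},
    2: {"tc": _TC_ACT_B,
        "defects": [DefectSpec("anterior", 0.4, isotopes="tl"),
                    DefectSpec("inferior", 0.2, isotopes="tl")]},
    3: {"tc": _TC_ACT_A,
        "defects": [DefectSpec("anterior", 0.2, isotopes="both"),
                    DefectSpec("septal", 0.4, isotopes="tl")]},
    4: {"tc": _TC_ACT_B,
        "defects": [DefectSpec("anterior", 0.4, isotopes="tl"),
                    DefectSpec("inferior", 0.2, isotopes="both")]},
}


def cardiac_phantom_spec(phantom_id: int = 3, grid=(64, 64, 64),
                         voxel_mm: float = 6.6, defects=None) -> PhantomSpec:
    """Spec for one of the four standard cardiac configurations.

    ``defects`` overrides the configuration's defect list (e.g. to study a
    single anterior defect in isolation).
    """
    if phantom_id not in CARDIAC_CONFIGS:
        raise ValueError(f"unknown phantom id {phantom_id}")
    cfg = CARDIAC_CONFIGS[phantom_id]
    return PhantomSpec(
        grid=tuple(grid), voxel_mm=voxel_mm,
        activities={"tc": dict(cfg["tc"]), "tl": dict(_TL_ACT)},
        defects=tuple(defects if defects is not None else cfg["defects"]),
    )


def jaszczak_phantom_spec(grid=(64, 64, 64), voxel_mm: float = 6.6) -> PhantomSpec:
    """Cylindrical water phantom with a cardiac insert and ANT+INF defects.

    Compartment activities are totals in MBq (anterior defect reversible,
    inferior irreversible).
    """
    return PhantomSpec(
        grid=tuple(grid), voxel_mm=voxel_mm,
        geometry=copy.deepcopy(DEFAULT_JASZCZAK_GEOMETRY),
        activities={
            "tl": {"myocardium": 8.18, "ventricle": 0.34,
                   "defect_anterior": 0.04, "defect_inferior": 0.04},
            "tc": {"myocardium": 35.96, "ventricle": 1.25,
                   "defect_inferior": 0.17},
        },
        defects=(DefectSpec("anterior", 0.0, isotopes="tl"),
                 DefectSpec("inferior", 0.0, isotopes="both")),
        activity_mode="total",
    )


@dataclass
class CardiacPhantom:
    """Voxelised phantom: paired activity volumes, attenuation and labels."""

    tc: ActivityVolume
    tl: ActivityVolume
    mu_map: AttenuationMap
    organs: np.ndarray                    # organ label grid
    defect_masks: tuple                   # ((DefectSpec, bool grid), ...)
    spec: PhantomSpec

    def defect_mask(self, sector: str) -> np.ndarray:
        for d, mask in self.defect_masks:
            if d.sector == sector:
                return mask
        raise KeyError(f"no {sector} defect in this phantom")

    @property
    def voxel_mm(self) -> float:
        return self.spec.voxel_mm


# ---------------------------------------------------------------------------
# Voxelisation helpers
# ---------------------------------------------------------------------------

def _grids_mm(shape, voxel_mm):
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_mm for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xx, yy, zz, center, semi):
    cx, cy, cz = center
    ax, ay, az = semi
    if min(semi) <= 0:
        raise ValueError("ellipsoid semi-axes must be positive")
    return (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
            + ((zz - cz) / az) ** 2) <= 1.0


def _heart_masks(xx, yy, zz, heart):
    cx, cy, cz = heart["center"]
    ax, ay, az = heart["outer_semi"]
    wall = heart["wall_mm"]
    if wall <= 0:
        raise ValueError("myocardial wall thickness must be positive")
    if wall >= min(ax, ay, az):
        raise ValueError("wall thickness exceeds the heart semi-axes")
    base_cut = heart.get("base_frac", 0.5) * az
    lx, ly, lz = xx - cx, yy - cy, zz - cz
    below_base = lz <= base_cut
    outer = ((lx / ax) ** 2 + (ly / ay) ** 2 + (lz / az) ** 2) <= 1.0
    inner = ((lx / (ax - wall)) ** 2 + (ly / (ay - wall)) ** 2
             + (lz / (az - wall)) ** 2) <= 1.0
    cavity = inner & below_base
    shell = outer & below_base & ~cavity
    return shell, cavity, (lx, ly, lz)


def _defect_mask(shell, local, defect: DefectSpec):
    lx, ly, lz = local
    angle = np.degrees(np.arctan2(ly, lx)) % 360.0
    center = _SECTOR_ANGLES[defect.sector]
    dist = np.abs((angle - center + 180.0) % 360.0 - 180.0)
    in_sector = dist <= defect.extent_deg / 2.0
    in_axial = np.abs(lz - defect.axial_center_mm) <= defect.axial_mm / 2.0
    return shell & in_sector & in_axial


def _check_disjoint(masks: dict) -> None:
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            n = int(np.count_nonzero(masks[a] & masks[b]))
            if n:
                raise ValueError(
                    f"ambiguous phantom geometry: organs {a!r} and {b!r} "
                    f"overlap in {n} voxels"
                )


def _assemble(spec: PhantomSpec, organs, material, shell, cavity, local,
              reference_kev: float, table: MaterialTable | None):
    """Common activity / attenuation assembly for both phantom families."""
    table = table or default_material_table()
    voxel_cm3 = (spec.voxel_mm / 10.0) ** 3

    organ_of = {"lung": ORGAN_IDS["lung"], "liver": ORGAN_IDS["liver"],
                "myocardium": ORGAN_IDS["myocardium"],
                "ventricle": ORGAN_IDS["ventricle"],
                "background": ORGAN_IDS["background"]}

    defect_masks = []
    all_defects = np.zeros(spec.grid, dtype=bool)
    for defect in spec.defects:
        mask = _defect_mask(shell, local, defect)
        if not mask.any():
            raise ValueError(f"{defect.sector} defect covers no voxels")
        defect_masks.append((defect, mask))
        all_defects |= mask

    volumes = {}
    for iso in ("tc", "tl"):
        act = np.zeros(spec.grid, dtype=np.float32)
        per_organ = spec.activities.get(iso, {})
        for organ, value in per_organ.items():
            if organ.startswith("defect_"):
                continue
            oid = organ_of.get(organ)
            if oid is None:
                raise ValueError(f"unknown organ {organ!r} in activities")
            mask = organs == oid
            if spec.activity_mode == "total":
                # compartment totals exclude the fillable defect inserts
                n = int(np.count_nonzero(mask & ~all_defects)) \
                    if oid == ORGAN_IDS["myocardium"] else int(np.count_nonzero(mask))
                conc = value / (n * voxel_cm3) if n else 0.0
            else:
                conc = value
            act[mask] = conc
        myo_conc = float(act[(organs == ORGAN_IDS["myocardium"])
                             & ~all_defects].max()) \
            if np.any((organs == ORGAN_IDS["myocardium"]) & ~all_defects) else 0.0
        for defect, mask in defect_masks:
            if defect.isotopes in (iso, "both"):
                if spec.activity_mode == "total":
                    tot = per_organ.get(f"defect_{defect.sector}", 0.0)
                    conc = tot / (int(np.count_nonzero(mask)) * voxel_cm3)
                else:
                    conc = defect.fraction * myo_conc
                act[mask] = conc
        volumes[iso] = ActivityVolume(act, spec.voxel_mm,
                                      isotope=TC99M.isotope if iso == "tc"
                                      else TL201.isotope)

    mu = np.zeros(spec.grid, dtype=np.float32)
    for lab, mat in enumerate(_MATERIALS):
        if mat:
            mu[material == lab] = table.mu_at(mat, reference_kev)
    mu_map = AttenuationMap(mu, spec.voxel_mm, reference_kev,
                            labels=material, materials=_MATERIALS)
    return CardiacPhantom(volumes["tc"], volumes["tl"], mu_map, organs,
                          tuple(defect_masks), spec)


def build_cardiac_phantom(spec: PhantomSpec, reference_kev: float = 140.0,
                          table: MaterialTable | None = None) -> CardiacPhantom:
    """Voxelise the torso configuration described by ``spec``."""
    xx, yy, zz = _grids_mm(spec.grid, spec.voxel_mm)
    geo = spec.geometry
    body = _ellipsoid(xx, yy, zz, **geo["body"])
    lungs = (_ellipsoid(xx, yy, zz, **geo["lung_left"])
             | _ellipsoid(xx, yy, zz, **geo["lung_right"]))
    liver = _ellipsoid(xx, yy, zz, **geo["liver"])
    sx, sy = geo["spine"]["center"]
    spine = (((xx - sx) ** 2 + (yy - sy) ** 2)
             <= geo["spine"]["radius"] ** 2) & body
    shell, cavity, local = _heart_masks(xx, yy, zz, geo["heart"])
    heart = shell | cavity
    _check_disjoint({"lungs": lungs, "liver": liver, "heart": heart,
                     "spine": spine})
    for name, mask in (("lungs", lungs), ("liver", liver), ("heart", heart)):
        if np.any(mask & ~body):
            raise ValueError(f"{name} extends outside the body ellipsoid")

    organs = np.zeros(spec.grid, dtype=np.int8)
    organs[body] = ORGAN_IDS["background"]
    organs[lungs] = ORGAN_IDS["lung"]
    organs[liver] = ORGAN_IDS["liver"]
    organs[shell] = ORGAN_IDS["myocardium"]
    organs[cavity] = ORGAN_IDS["ventricle"]
    organs[spine] = ORGAN_IDS["bone"]

    material = np.full(spec.grid, _AIR, dtype=np.int8)
    material[body] = _SOFT
    material[lungs] = _LUNG
    material[spine] = _BONE
    return _assemble(spec, organs, material, shell, cavity, local,
                     reference_kev, table)


def build_jaszczak_phantom(spec: PhantomSpec, reference_kev: float = 140.0,
                           table: MaterialTable | None = None) -> CardiacPhantom:
    """Voxelise a cylindrical water phantom with the cardiac insert."""
    xx, yy, zz = _grids_mm(spec.grid, spec.voxel_mm)
    geo = spec.geometry
    cyl = geo["cylinder"]
    if cyl["radius"] <= 0 or cyl["half_height"] <= 0:
        raise ValueError("cylinder radius and height must be positive")
    body = ((xx ** 2 + yy ** 2) <= cyl["radius"] ** 2) \
        & (np.abs(zz) <= cyl["half_height"])
    organs = np.zeros(spec.grid, dtype=np.int8)
    organs[body] = ORGAN_IDS["background"]
    if "heart" in geo:
        shell, cavity, local = _heart_masks(xx, yy, zz, geo["heart"])
        if np.any((shell | cavity) & ~body):
            raise ValueError("cardiac insert extends outside the cylinder")
        organs[shell] = ORGAN_IDS["myocardium"]
        organs[cavity] = ORGAN_IDS["ventricle"]
    else:
        shell = np.zeros(spec.grid, dtype=bool)
        cavity = shell
        local = (xx, yy, zz)
    material = np.full(spec.grid, _AIR, dtype=np.int8)
    material[body] = _SOFT
    return _assemble(spec, organs, material, shell, cavity, local,
                     reference_kev, table)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """Acquisition protocol: geometry, windows and count targets.

    Count targets default to the full clinical-scale totals (76 Mcts in the
    Tc-99m window, 80 Mcts in the dual-study Tl-201 window, 10 Mcts in the
    pure-Tl-201 study); ``count_scale`` scales all three for smaller runs.
    """

    n_views: int = 64
    arc_deg: float = 360.0
    orbit_radius_mm: float = 250.0
    detector_shape: tuple = (64, 64)
    pixel_mm: float = 6.6
    tc_window: EnergyWindow = TC_WINDOW
    tl_window: EnergyWindow = TL_WINDOW
    tc_counts: float = 76e6
    tl_dual_counts: float = 80e6
    tl_pure_counts: float = 10e6
    count_scale: float = 1.0
    resolution_frac: float = 0.099

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("at least one view required")
        if min(self.tc_counts, self.tl_dual_counts, self.tl_pure_counts) <= 0 \
                or self.count_scale <= 0:
            raise ValueError("target counts must be positive")
        tl_lo, tl_hi = self.tl_window.bounds
        tc_lo, tc_hi = self.tc_window.bounds
        if tl_hi > tc_lo and tc_hi > tl_lo:
            raise ValueError("energy windows overlap")

    def geometry(self) -> Geometry:
        return Geometry.circular(self.n_views, self.arc_deg,
                                 self.orbit_radius_mm, self.detector_shape,
                                 self.pixel_mm)


@dataclass
class SimulatedStudy:
    """Noisy projections plus the noise-free expectations behind them."""

    tc: ProjectionSet
    tl_dual: ProjectionSet
    tl_pure: ProjectionSet
    expected_tc: ProjectionSet
    expected_tl_dual: ProjectionSet
    expected_tl_pure: ProjectionSet
    downscatter: ProjectionSet
    study: StudySpec
    seed: int


def add_poisson_noise(projections: ProjectionSet, target_total_counts: float,
                      seed: int) -> ProjectionSet:
    """Scale to the target total and draw independent Poisson counts."""
    if target_total_counts <= 0:
        raise ValueError("target counts must be positive")
    if np.any(projections.data < 0):
        raise ValueError("projection data must be non-negative")
    total = projections.total()
    if total <= 0:
        raise ValueError("cannot scale an all-zero projection set to "
                         "positive target counts")
    scale = target_total_counts / total
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(projections.data.astype(np.float64) * scale)
    out = projections.copy_with(noisy.astype(np.float32))
    out.meta = dict(projections.meta, noise_seed=int(seed),
                    count_scale_factor=float(scale))
    return out


def collapse_projections(projections: ProjectionSet, factor: int) -> ProjectionSet:
    """Sum factor x factor detector-bin blocks (total counts preserved)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("collapse factor must be a positive integer")
    if factor == 1:
        return projections
    nv, nu, nz = projections.data.shape
    if nu % factor or nz % factor:
        raise ValueError(f"detector grid {nu}x{nz} not divisible by {factor}")
    d = projections.data.reshape(nv, nu // factor, factor, nz // factor, factor)
    out = projections.copy_with(d.sum(axis=(2, 4)))
    out.pixel_mm = projections.pixel_mm * factor
    return out


def _scaled_noisy(expected: ProjectionSet, target: float, seed: int):
    if expected.total() <= 0:   # e.g. the Tc window of a pure-Tl phantom
        return expected.copy_with(np.zeros_like(expected.data))
    return add_poisson_noise(expected, target, seed)


def simulate_study(phantom: CardiacPhantom, study: StudySpec,
                   collimator: CollimatorModel | None = None,
                   mc_config=None, seed: int = 0,
                   table: MaterialTable | None = None) -> SimulatedStudy:
    """Simulate the simultaneous dual-isotope study and the matching
    pure-Tl-201 study.

    Tc-window expectation = Tc primaries + Tc self-scatter; dual-study
    Tl-window expectation additionally carries the Tc down-scatter term,
    which the pure study omits.  Each window is scaled to its target totals
    (times ``count_scale``) before Poisson sampling.  Self- and down-scatter
    are estimated with the Monte-Carlo engine from the true activity maps.
    """
    from .mcscatter import McConfig, simulate_scatter

    collimator = collimator or CollimatorModel()
    table = table or default_material_table()
    mc_config = mc_config or McConfig(photons=1_000_000, seed=seed)
    geometry = study.geometry()
    res = study.resolution_frac
    root = np.random.SeedSequence(seed)
    mc_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                for s in root.spawn(3)]
    noise_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in root.spawn(3)]

    def primaries(act, energy, window):
        eff = window_acceptance(energy, window, res)
        system = SpectSystem(geometry, phantom.mu_map, collimator, energy,
                             phantom.voxel_mm, efficiency=eff, table=table)
        return system.forward(act.values)

    def scatter(act, emission, window, mc_seed):
        import dataclasses
        cfg = dataclasses.replace(mc_config, seed=mc_seed)
        est, _ = simulate_scatter(act, phantom.mu_map, emission, window,
                                  geometry, collimator, cfg, table=table,
                                  resolution_frac=res)
        return est.data

    p_tc = primaries(phantom.tc, TC99M.energy_kev, study.tc_window)
    s_tc = scatter(phantom.tc, TC99M, study.tc_window, mc_seeds[0])
    p_tl = primaries(phantom.tl, TL201.energy_kev, study.tl_window)
    s_tl = scatter(phantom.tl, TL201, study.tl_window, mc_seeds[1])
    if phantom.tc.total() > 0:
        ds = scatter(phantom.tc, TC99M, study.tl_window, mc_seeds[2])
    else:
        ds = np.zeros_like(p_tl)

    def pset(data, window):
        return ProjectionSet(data, np.asarray(geometry.angles_deg),
                             geometry.orbit_radius_mm, geometry.pixel_mm,
                             window_center_kev=window.center_kev,
                             window_width_frac=window.width_frac)

    exp_tc = pset(p_tc + s_tc, study.tc_window)
    exp_tl_pure = pset(p_tl + s_tl, study.tl_window)
    exp_tl_dual = pset(p_tl + s_tl + ds, study.tl_window)

    scale = study.count_scale
    return SimulatedStudy(
        tc=_scaled_noisy(exp_tc, study.tc_counts * scale, noise_seeds[0]),
        tl_dual=_scaled_noisy(exp_tl_dual, study.tl_dual_counts * scale,
                              noise_seeds[1]),
        tl_pure=_scaled_noisy(exp_tl_pure, study.tl_pure_counts * scale,
                              noise_seeds[2]),
        expected_tc=exp_tc,
        expected_tl_dual=exp_tl_dual,
        expected_tl_pure=exp_tl_pure,
        downscatter=pset(ds, study.tl_window),
        study=study,
        seed=seed,
    )
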