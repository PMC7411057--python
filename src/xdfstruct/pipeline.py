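"""Study orchestration: phantoms -> G(xi) + MCL -> two-bin dark-field -> ratio.

``run_material`` runs the full chain for one material; ``correlate`` ranks
the spectral dark-field ratio against the mean chord length across a
material family; ``reproduce_worked_examples`` recomputes the published
reference numbers (autocorrelation lengths from the interferometer
geometry, and the wavelength-normalized dark-field signals) from their
printed inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .autocorr import CorrelationProfile, correlation_profile
from .chords import ChordDistribution, binarize, mean_chord_length
from .darkfield import (
    BinResult,
    DarkFieldResult,
    MaterialModel,
    normalized_logD,
    polychromatic_darkfield,
    spectral_ratio,
)
from .spectral import (
    EnergyBin,
    HC_KEV_ANGSTROM,
    InterferometerGeometry,
    SpectralTable,
    correlation_length,
    effective_bin_spectrum,
    effective_correlation_length,
    simulate_source_spectrum,
    visibility_model,
    weighted_energy,
)
from .volumes import (
    PhantomSpec,
    Volume3D,
    add_microct_noise,
    make_hollow_spheres,
    make_slab,
    make_solid_spheres,
    make_voronoi_foam,
)
from . import io as vio

__all__ = [
    "MaterialEntry",
    "StudyConfig",
    "MaterialRecord",
    "default_study_config",
    "build_phantom",
    "run_material",
    "correlate",
    "run_study",
    "reproduce_worked_examples",
]

_MAKERS = {
    "solid_spheres": make_solid_spheres,
    "hollow_spheres": make_hollow_spheres,
    "voronoi_foam": make_voronoi_foam,
    "slab": make_slab,
}


@dataclass
class MaterialEntry:
    """One material of the study: a phantom spec (or volume path) + physics."""

    name: str
    phantom: PhantomSpec | None = None
    volume_path: str | None = None
    sigma0: float = 5.0e4  # 1/(m·Å²)
    thickness_m: float = 0.005
    blur_sigma_um: float = 0.0
    noise_sd: float = 0.0
    noise_seed: int = 0


@dataclass
class StudyConfig:
    geometry: InterferometerGeometry = field(
        default_factory=lambda: InterferometerGeometry(
            d_S_G2=0.571, p_G2=10.0, design_energy=45.0
        )
    )
    kVp: float = 120.0
    al_filtration_mm: float = 2.0
    source_csv: str | None = None
    visibility_csv: str | None = None
    bins: tuple[EnergyBin, EnergyBin] = (
        EnergyBin(23.0, 64.0, "low"),
        EnergyBin(64.0, 120.0, "high"),
    )
    response_fwhm_keV: float = 8.0
    quadrature_step_keV: float = 0.5
    n_lines: int = 10000
    stereology_seed: int = 0
    average_projection_axes: bool = True  # isotropic samples: 3-axis G averaging
    materials: list[MaterialEntry] = field(default_factory=list)
    output_dir: str = "study_out"

    def source_spectrum(self) -> SpectralTable:
        if self.source_csv:
            return SpectralTable.from_csv(self.source_csv, kind="fluence")
        return simulate_source_spectrum(self.kVp, self.al_filtration_mm)

    def visibility_spectrum(self) -> SpectralTable:
        if self.visibility_csv:
            return SpectralTable.from_csv(self.visibility_csv, kind="visibility")
        return visibility_model(design_energy=self.geometry.design_energy)


@dataclass
class MaterialRecord:
    name: str
    chords: ChordDistribution
    profile: CorrelationProfile
    darkfield: DarkFieldResult

    @property
    def mcl_um(self) -> float:
        return self.chords.mcl

    @property
    def ratio(self) -> float:
        return self.darkfield.ratio_low_over_high

    def summary(self) -> dict:
        out = {
            "name": self.name,
            "mcl_um": self.chords.mcl,
            "mcl_se_um": self.chords.mcl_se,
            "n_chords": self.chords.n_chords,
            "n_excluded": self.chords.n_excluded,
            "ratio_low_over_high": self.darkfield.ratio_low_over_high,
        }
        for label, br in self.darkfield.bins.items():
            out[label] = {
                "D": br.D,
                "neg_log_D": br.neg_log_D,
                "xi_w_um": br.xi_w_um,
                "lambda_w_A": br.lambda_w_A,
            }
        return out


def default_study_config(seed: int = 0) -> StudyConfig:
    """Five closed-cell foams with mean chord lengths spanning ~12-55 μm.

    Grid 128³ at 2 μm voxels (256 μm box). The seed counts place the
    Poisson-Voronoi cell sizes in the regime where the spectral dark-field
    ratio responds steeply to structure size; the boundary-exclusion rule
    makes much larger cells unmeasurable in this box, so the family covers
    the lower part of the published foam/microsphere range.
    """
    n_seed_family = [2000, 800, 300, 100, 30]
    materials = [
        MaterialEntry(
            name=f"foam_{n:04d}",
            phantom=PhantomSpec(
                kind="voronoi_foam",
                shape=(128, 128, 128),
                voxel_size=2.0,
                n_seeds=n,
                wall_thickness_um=4.0,
                seed=seed * 1000 + i,
            ),
        )
        for i, n in enumerate(n_seed_family)
    ]
    return StudyConfig(materials=materials, stereology_seed=seed)


def build_phantom(entry: MaterialEntry):
    """Materialize a MaterialEntry into (Volume3D, PhaseMap or None)."""
    if entry.volume_path is not None:
        vol = vio.load_volume(entry.volume_path)
        return vol, None
    if entry.phantom is None:
        raise ValueError(f"material {entry.name!r} has neither phantom nor volume_path")
    maker = _MAKERS[entry.phantom.kind]
    vol, pm = maker(entry.phantom)
    if entry.blur_sigma_um > 0 or entry.noise_sd > 0:
        vol = add_microct_noise(
            vol, entry.blur_sigma_um, entry.noise_sd, seed=entry.noise_seed
        )
        pm = None  # degraded volume must be re-segmented
    return vol, pm


def run_material(cfg: StudyConfig, entry: MaterialEntry) -> MaterialRecord:
    """Full per-material chain; deterministic for a fixed config."""
    vol, pm = build_phantom(entry)
    if pm is None:
        pm = binarize(vol, "otsu")
    profile = correlation_profile(
        vol, boundary="zero_pad", beam_axis=0,
        average_axes=cfg.average_projection_axes,
    )
    chords = mean_chord_length(pm, n_lines=cfg.n_lines, seed=cfg.stereology_seed)
    phi = cfg.source_spectrum()
    vis = cfg.visibility_spectrum()
    mat = MaterialModel(
        sigma0=entry.sigma0, thickness_t=entry.thickness_m, G_profile=profile
    )
    bins_out: dict[str, BinResult] = {}
    for b in cfg.bins:
        phi_eff = effective_bin_spectrum(phi, b, cfg.response_fwhm_keV)
        xi_w = effective_correlation_length(
            phi_eff, vis, b, cfg.geometry, step=cfg.quadrature_step_keV
        )
        E_w = weighted_energy(phi_eff, vis, b, step=cfg.quadrature_step_keV)
        D = polychromatic_darkfield(
            mat, phi_eff, vis, b, cfg.geometry, step=cfg.quadrature_step_keV
        )
        label = b.label or f"{b.E1:g}-{b.E2:g}"
        bins_out[label] = BinResult(
            D=D,
            neg_log_D=float(-np.log(D)),
            xi_w_um=xi_w,
            lambda_w_A=HC_KEV_ANGSTROM / E_w,
        )
    labels = list(bins_out)
    ratio = spectral_ratio(bins_out[labels[0]].neg_log_D, bins_out[labels[1]].neg_log_D)
    return MaterialRecord(
        name=entry.name,
        chords=chords,
        profile=profile,
        darkfield=DarkFieldResult(bins=bins_out, ratio_low_over_high=ratio),
    )


def correlate(records: list[MaterialRecord]) -> dict:
    """Rank correlation of the spectral ratio against MCL across materials."""
    if len(records) < 3:
        raise ValueError("need at least 3 materials for a correlation")
    mcl = np.array([r.mcl_um for r in records])
    ratio = np.array([r.ratio for r in records])
    scatter = pd.DataFrame(
        {"material": [r.name for r in records], "mcl_um": mcl, "ratio": ratio}
    ).sort_values("mcl_um")
    if np.all(ratio == ratio[0]):
        return {"spearman_rho": float("nan"), "monotone_increasing": False,
                "note": "all ratios tied; correlation undefined", "scatter": scatter}
    rho, p = spearmanr(mcl, ratio)
    order = np.argsort(mcl)
    monotone = bool(np.all(np.diff(ratio[order]) > 0))
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "monotone_increasing": monotone,
        "scatter": scatter,
    }


def run_study(cfg: StudyConfig, write: bool = False) -> dict:
    """Run every material and the cross-material correlation; optionally write outputs."""
    records = [run_material(cfg, entry) for entry in cfg.materials]
    report = correlate(records)
    report["materials"] = [r.summary() for r in records]
    if write:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in records:
            r.profile.to_csv(out / f"{r.name}_profile.csv")
            (out / f"{r.name}.json").write_text(json.dumps(r.summary(), indent=2))
            labels = list(r.darkfield.bins)
            rows.append(
                {
                    "material": r.name,
                    "mcl_um": r.mcl_um,
                    "neg_log_D_low": r.darkfield.bins[labels[0]].neg_log_D,
                    "neg_log_D_high": r.darkfield.bins[labels[1]].neg_log_D,
                    "ratio": r.ratio,
                    "xi_w_low_um": r.darkfield.bins[labels[0]].xi_w_um,
                    "xi_w_high_um": r.darkfield.bins[labels[1]].xi_w_um,
                }
            )
        pd.DataFrame(rows).to_csv(out / "study_summary.csv", index=False)
        report["scatter"].to_csv(out / "scatter.csv", index=False)
    return report


def _load_worked_constants() -> dict:
    with resources.files("xdfstruct.data").joinpath("worked_examples.json").open() as fh:
        return json.load(fh)


def reproduce_worked_examples() -> pd.DataFrame:
    """Recompute the published reference numbers from their printed inputs.

    Returns a tidy table with one row per quantity: the autocorrelation
    length at each bin's weighted energy (from the printed geometry), and
    -lnD/lambda_w² for each material and bin (from the printed -ln D and
    wavelengths), against the published values rounded to 2 decimals.
    """
    c = _load_worked_constants()
    geom = InterferometerGeometry(
        d_S_G2=c["geometry"]["d_S_G2_m"],
        p_G2=c["geometry"]["p_G2_um"],
        design_energy=c["geometry"]["design_energy_keV"],
    )
    rows = []
    for bin_label, binfo in c["bins"].items():
        xi = correlation_length(binfo["E_w_keV"], geom)
        rows.append(
            {
                "quantity": f"xi_w_{bin_label}_um",
                "material": "",
                "bin": bin_label,
                "computed": round(xi, 2),
                "published": binfo["xi_w_um"],
            }
        )
    for mat_name, vals in c["neg_log_D"].items():
        for bin_label, neg_log in vals.items():
            lam = c["bins"][bin_label]["lambda_w_A"]
            val = normalized_logD(neg_log, lam)
            rows.append(
                {
                    "quantity": "neg_log_D_over_lambda2",
                    "material": mat_name,
                    "bin": bin_label,
                    "computed": round(val, 2),
                    "published": c["published_normalized"][mat_name][bin_label],
                }
            )
    df = pd.DataFrame(rows)
    df["match"] = df["computed"] == df["published"]
    return df


def load_config(path: str | Path) -> StudyConfig:
    """Build a StudyConfig from a YAML/JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    geom = raw.get("geometry", {})
    materials = []
    for m in raw.get("materials", []):
        spec = None
        if "phantom" in m:
            spec = PhantomSpec(**m["phantom"])
        materials.append(
            MaterialEntry(
                name=m["name"],
                phantom=spec,
                volume_path=m.get("volume_path"),
                sigma0=m.get("sigma0", 5.0e4),
                thickness_m=m.get("thickness_m", 0.005),
                blur_sigma_um=m.get("blur_sigma_um", 0.0),
                noise_sd=m.get("noise_sd", 0.0),
                noise_seed=m.get("noise_seed", 0),
            )
        )
    bins = tuple(
        EnergyBin(b["E1"], b["E2"], b.get("label", "")) for b in raw.get(
            "bins", [{"E1": 23.0, "E2": 64.0, "label": "low"},
                     {"E1": 64.0, "E2": 120.0, "label": "high"}]
        )
    )
    return StudyConfig(
        geometry=InterferometerGeometry(
            d_S_G2=geom.get("d_S_G2", 0.571),
            p_G2=geom.get("p_G2", 10.0),
            design_energy=geom.get("design_energy", 45.0),
        ),
        kVp=raw.get("kVp", 120.0),
        al_filtration_mm=raw.get("al_filtration_mm", 2.0),
        source_csv=raw.get("source_csv"),
        visibility_csv=raw.get("visibility_csv"),
        bins=bins,
        response_fwhm_keV=raw.get("response_fwhm_keV", 8.0),
        quadrature_step_keV=raw.get("quadrature_step_keV", 0.5),
        n_lines=raw.get("n_lines", 10000),
        stereology_seed=raw.get("stereology_seed", 0),
        materials=materials,
        output_dir=raw.get("output_dir", "study_out"),
    )
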