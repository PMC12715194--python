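"""Synthetic-data generators with planted ground truth.

Every input the analysis chain consumes can be generated here at desk
scale: peptide-level footprinting intensity tables, temperature-ramped
gating currents, two-state CD melts, tryptophan emission spectra and
Calpha coordinate ensembles with hydration waters.  Each generator is
deterministic given its seed and admits a zero-noise mode in which the
matching estimator recovers the generating parameters to numerical
precision.

Ground truth is returned as sidecar tables next to (never inside) the
input schema, so downstream stages cannot read the answer.

Footprinting noise model
------------------------
Label-free DIA intensities are positive and roughly log-normal, and the
dominant variability is at the run level (injection amount, ionisation,
sample handling) and therefore shared by every precursor measured in the
same run.  Each recorded intensity is the expected value times a
run-level log-normal factor with coefficient of variation ``noise_cv``
(shared per condition x temperature x replicate) times an independent
per-record measurement factor with CV ``noise_cv * measurement_cv_fraction``.
Because the oxidized and unmodified forms of a peptide are quantified in
the same run, the run-level factor cancels exactly in the oxidation
efficiency ratio; only the smaller measurement component propagates into
fold changes, which is what makes the +/-20% FC window a usable calling
threshold at CVs typical of label-free quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_KCAL, celsius_to_kelvin
from .errors import ConfigError
from .ensemble_analysis import CoordinateEnsemble
from .spectroscopy import EmissionSpectrum, MeltCurve, two_state_signal
from .thermo import CurrentTrace

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

TEMPERATURES_C = (4, 30)
CONDITIONS = ("C", "F", "O")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# footprinting

@dataclass
class FootprintSimConfig:
    """Design of a synthetic footprinting experiment.

    Three treatments (C untreated, F Fe(II)-EDTA only, O Fenton
    oxidation) at two temperatures with ``n_replicates`` biological
    replicates each.  ``fc_planted`` maps residue positions to the true
    4C/30C fold change of their relative oxidation; unlisted monitored
    sites (members of the exposure ground-truth lists) default to 1.0.
    """

    n_residues: int = 800
    sites_exposed: tuple[int, ...] = ()
    sites_buried: tuple[int, ...] = ()
    fc_planted: dict[int, float] = field(default_factory=dict)
    n_replicates: int = 3
    true_oxi_fraction_base: float = 0.30
    ctrl_oxi_fraction: float = 0.05
    noise_cv: float = 0.0
    measurement_cv_fraction: float = 1.0 / 3.0
    nominal_intensity: float = 1.0e6
    peptide_halfwidth: int = 4
    seed: int = 0

    def __post_init__(self):
        if set(self.sites_exposed) & set(self.sites_buried):
            raise ConfigError("exposed and buried site lists overlap")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not (0 < self.true_oxi_fraction_base < 1):
            raise ConfigError("true_oxi_fraction_base must lie in (0, 1)")
        if self.n_replicates < 3:
            raise ConfigError("the design uses >=3 biological replicates")
        for site, fc in self.fc_planted.items():
            if fc <= 0:
                raise ConfigError(f"planted FC at site {site} must be positive")
            if fc * self.true_oxi_fraction_base >= 1:
                raise ConfigError(
                    f"planted FC {fc} at site {site} drives the oxidized "
                    "fraction beyond 1; lower the base fraction")
        sites = self.monitored_sites()
        if sites and (min(sites) < 1 or max(sites) > self.n_residues):
            raise ConfigError("monitored sites must lie within the protein")

    def monitored_sites(self) -> list[int]:
        return sorted(set(self.fc_planted) | set(self.sites_exposed)
                      | set(self.sites_buried))

    def true_fc(self, site: int) -> float:
        return self.fc_planted.get(site, 1.0)


@dataclass
class FootprintDataset:
    """A synthetic peptide intensity table plus its ground-truth sidecar."""

    table: pd.DataFrame
    truth: pd.DataFrame
    protein_sequence: str
    config: FootprintSimConfig


def gen_footprint_dataset(config: FootprintSimConfig) -> FootprintDataset:
    """Generate oxidized/unmodified intensity pairs for every monitored site.

    Each monitored residue is covered by one tryptic-like peptide
    (+/- ``peptide_halfwidth`` residues).  The oxidized fraction of the
    O treatment at 30 C is ``true_oxi_fraction_base``; at 4 C it is the
    base times the planted FC, while both controls share a constant
    background fraction at both temperatures, so the planted FC is the
    exact population value of the full Oxi% -> Relative Oxi% -> FC chain.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    protein = "".join(rng.choice(list(AA_ALPHABET), size=cfg.n_residues))
    sites = cfg.monitored_sites()
    if not sites:
        raise ConfigError("no monitored sites: plant at least one FC")

    meas_cv = cfg.noise_cv * cfg.measurement_cv_fraction
    run_factor = {
        (cond, t, rep): f
        for (cond, t, rep), f in zip(
            [(c, t, r) for c in CONDITIONS for t in TEMPERATURES_C
             for r in range(1, cfg.n_replicates + 1)],
            _lognormal_factors(rng, cfg.noise_cv,
                               len(CONDITIONS) * 2 * cfg.n_replicates))
    }

    rows = []
    for site in sites:
        start = max(1, site - cfg.peptide_halfwidth)
        end = min(cfg.n_residues, site + cfg.peptide_halfwidth)
        seq = protein[start - 1:end]
        fc = cfg.true_fc(site)
        for cond in CONDITIONS:
            for t in TEMPERATURES_C:
                if cond == "O":
                    frac = cfg.true_oxi_fraction_base * (fc if t == 4 else 1.0)
                else:
                    frac = cfg.ctrl_oxi_fraction
                for rep in range(1, cfg.n_replicates + 1):
                    run = run_factor[(cond, t, rep)]
                    eps = _lognormal_factors(rng, meas_cv, 2)
                    i_oxi = cfg.nominal_intensity * frac * run * eps[0]
                    i_nak = cfg.nominal_intensity * (1 - frac) * run * eps[1]
                    rows.append((seq, start, site, 1, cond, t, rep, i_oxi))
                    rows.append((seq, start, pd.NA, 0, cond, t, rep, i_nak))
    table = pd.DataFrame(rows, columns=[
        "peptide_sequence", "protein_position", "oxidized_residue",
        "n_oxidations_on_peptide", "condition", "temperature_C",
        "replicate", "intensity"])
    table["oxidized_residue"] = table["oxidized_residue"].astype("Int64")

    def label(site):
        if site in cfg.sites_exposed:
            return "more_exposed"
        if site in cfg.sites_buried:
            return "more_buried"
        return "unchanged"

    truth = pd.DataFrame({
        "residue": sites,
        "amino_acid": [protein[s - 1] for s in sites],
        "fc_true": [cfg.true_fc(s) for s in sites],
        "label": [label(s) for s in sites],
    })
    return FootprintDataset(table=table, truth=truth,
                            protein_sequence=protein, config=cfg)


# ---------------------------------------------------------------------------
# gating currents

@dataclass
class GatingSimConfig:
    """Two-state cold-activated gating ramp.

    Defaults describe a strongly cold-activated channel (dH = -100
    kcal/mol, dS chosen for a half-activation temperature near 7 C) ramped
    over 4-20 C, the window in which the open probability traverses the
    transition without saturating.
    """

    dH: float = -100.0          # kcal/mol (negative: cold-activated)
    dS: float = -0.357          # kcal/(mol.K)
    temp_grid_C: tuple[float, ...] = tuple(float(t) for t in range(4, 21))
    i_max: float = 2000.0       # pA at saturating menthol
    noise_sd: float = 0.0       # pA
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.temp_grid_C, dtype=float)
        if grid.size == 0:
            raise ConfigError("temp_grid_C must not be empty")
        d = np.diff(grid)
        if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigError("temp_grid_C must be strictly monotone")
        if self.i_max <= 0:
            raise ConfigError("i_max must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def ln_keq(temperatures_K, dH: float, dS: float):
    """ln Keq = -dH/(R T) + dS/R for the two-state gating equilibrium."""
    t = np.asarray(temperatures_K, dtype=float)
    return -dH / (R_KCAL * t) + dS / R_KCAL


def gen_current_ramp(config: GatingSimConfig) -> CurrentTrace:
    """current(T) = i_max * Keq/(1+Keq) + Gaussian noise."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t_c = np.asarray(cfg.temp_grid_C, dtype=float)
    lk = ln_keq(celsius_to_kelvin(t_c), cfg.dH, cfg.dS)
    po = 1.0 / (1.0 + np.exp(-np.clip(lk, -500, 500)))
    current = cfg.i_max * po
    if cfg.noise_sd > 0:
        current = current + rng.normal(0.0, cfg.noise_sd, size=current.shape)
    return CurrentTrace(temperature_C=t_c, current=current,
                        menthol_max_current=cfg.i_max)


# ---------------------------------------------------------------------------
# CD melts and emission spectra

@dataclass
class MeltSimConfig:
    """Two-state thermal melt with linear baselines.

    Defaults mirror a cold-populated transition of an alpha-helical
    domain followed at 222 nm over a 10-50 C scan: dH = -44 kcal/mol,
    midpoint 31.3 C, baselines on a mean-residue-ellipticity scale.
    """

    dH_unfold: float = -44.0    # kcal/mol
    t_mid_C: float = 31.3
    temp_grid_C: tuple[float, ...] = tuple(float(t) for t in range(10, 51, 2))
    baseline_folded: tuple[float, float] = (-12000.0, 20.0)    # intercept, slope/C
    baseline_unfolded: tuple[float, float] = (-4000.0, 5.0)
    noise_sd: float = 0.0       # signal units
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.temp_grid_C, dtype=float)
        if grid.size < 5:
            raise ConfigError("melt grid needs >=5 temperatures")
        if not (grid.min() <= self.t_mid_C <= grid.max()):
            raise ConfigError("t_mid_C must lie inside the temperature grid")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    @property
    def transition_amplitude(self) -> float:
        """Baseline separation at the midpoint (signal units)."""
        bf0, bf1 = self.baseline_folded
        bu0, bu1 = self.baseline_unfolded
        t = self.t_mid_C
        return abs((bf0 + bf1 * t) - (bu0 + bu1 * t))


def gen_cd_melt(config: MeltSimConfig) -> MeltCurve:
    """Baseline mixture weighted by the two-state unfolded fraction."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.temp_grid_C, dtype=float)
    bf0, bf1 = cfg.baseline_folded
    bu0, bu1 = cfg.baseline_unfolded
    signal = two_state_signal(t, cfg.dH_unfold, cfg.t_mid_C, bf0, bf1, bu0, bu1)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    return MeltCurve(temperature_C=t, signal=signal)


def gen_emission_spectra(peaks_by_temp: dict[float, float],
                         wavelengths_nm=None, width_nm: float = 12.0,
                         amplitude: float = 1000.0, noise_sd: float = 0.0,
                         seed: int = 0) -> list[EmissionSpectrum]:
    """Gaussian tryptophan emission bands with planted peak positions.

    ``peaks_by_temp`` maps temperature (C) to the true peak wavelength
    (nm); a cooling-induced blue shift is planted by decreasing peaks at
    lower temperatures.
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(300.0, 400.0 + 0.5, 1.0)
    wl = np.asarray(wavelengths_nm, dtype=float)
    rng = np.random.default_rng(seed)
    spectra = []
    for t_c in sorted(peaks_by_temp):
        peak = peaks_by_temp[t_c]
        y = amplitude * np.exp(-0.5 * ((wl - peak) / width_nm) ** 2)
        if noise_sd > 0:
            y = np.clip(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0, None)
        spectra.append(EmissionSpectrum(wavelength_nm=wl.copy(), intensity=y,
                                        temperature_C=float(t_c)))
    return spectra


# ---------------------------------------------------------------------------
# coordinate ensembles

@dataclass
class EnsembleSimConfig:
    """Gaussian-fluctuation tetramer ensemble with planted hydration.

    Residues sit on rings around the z (channel) axis at radii
    ``ring_radii`` and axial spacing ``z_spacing`` -- a deliberately
    coarse, well-separated desk-scale geometry, not a physical backbone.
    Each residue fluctuates isotropically with its own sigma.  Planted
    waters co-move with their residue at ``water_distance`` (< contact
    cutoff) and decoy bulk waters at ``bulk_distance`` (> cutoff), so the
    per-residue contact count equals the planted count exactly.
    """

    n_residues: int = 12
    n_subunits: int = 4
    n_snapshots: int = 50
    sigma: float | tuple[float, ...] = 0.8        # A, scalar or per-residue
    ring_radii: float | tuple[float, ...] = 25.0  # A, scalar or per-residue
    z_spacing: float = 12.0
    planted_water_counts: tuple[int, ...] | None = None
    water_distance: float = 2.5
    bulk_waters_per_residue: int = 2
    bulk_distance: float = 6.5
    seed: int = 0

    def __post_init__(self):
        if self.n_snapshots < 1:
            raise ConfigError("need at least one snapshot")
        if self.n_subunits < 1 or self.n_residues < 1:
            raise ConfigError("need >=1 subunit and residue")
        if np.any(np.asarray(self.sigma) < 0):
            raise ConfigError("sigma must be >= 0")
        if self.planted_water_counts is not None:
            counts = np.asarray(self.planted_water_counts)
            if counts.size != self.n_residues:
                raise ConfigError("planted_water_counts must have one entry "
                                  "per residue")
            if np.any(counts < 0):
                raise ConfigError("water counts must be >= 0")

    def sigma_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.sigma, dtype=float),
                               (self.n_residues,)).copy()

    def radii_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.ring_radii, dtype=float),
                               (self.n_residues,)).copy()


def _unit_directions(k: int) -> np.ndarray:
    """k well-spread unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def gen_coordinate_ensemble(config: EnsembleSimConfig) -> CoordinateEnsemble:
    """Build the ensemble described by :class:`EnsembleSimConfig`."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S, N, M = cfg.n_subunits, cfg.n_residues, cfg.n_snapshots
    radii = cfg.radii_array()
    sigma = cfg.sigma_array()

    z = (np.arange(N) - (N - 1) / 2.0) * cfg.z_spacing
    angles = 2 * np.pi * np.arange(S) / S
    ref = np.empty((S, N, 3))
    for s, ang in enumerate(angles):
        ref[s, :, 0] = radii * np.cos(ang)
        ref[s, :, 1] = radii * np.sin(ang)
        ref[s, :, 2] = z

    disp = rng.normal(0.0, 1.0, size=(M, S, N, 3)) * sigma[None, None, :, None]
    coords = ref[None] + disp

    waters = None
    counts = (np.zeros(N, dtype=int) if cfg.planted_water_counts is None
              else np.asarray(cfg.planted_water_counts, dtype=int))
    n_shell = int(counts.sum()) * S
    n_bulk = cfg.bulk_waters_per_residue * N * S
    if n_shell + n_bulk > 0:
        waters = []
        shell_dirs = {n: _unit_directions(int(counts[n]))
                      for n in range(N) if counts[n] > 0}
        bulk_dirs = _unit_directions(max(cfg.bulk_waters_per_residue, 1))
        for m in range(M):
            pts = []
            for s in range(S):
                for n in range(N):
                    ca = coords[m, s, n]
                    if counts[n] > 0:
                        pts.append(ca + cfg.water_distance * shell_dirs[n])
                    if cfg.bulk_waters_per_residue > 0:
                        pts.append(ca + cfg.bulk_distance
                                   * bulk_dirs[:cfg.bulk_waters_per_residue])
            waters.append(np.concatenate(pts, axis=0) if pts
                          else np.empty((0, 3)))
    return CoordinateEnsemble(coords=coords, waters=waters, reference=ref)


# ---------------------------------------------------------------------------
# full hypothesis-consistent study

@dataclass
class HypothesisStudy:
    """A complete synthetic study generated under the exposure hypothesis."""

    footprint: FootprintDataset
    gating: dict[tuple[int, str], list[CurrentTrace]]  # (site, residue) -> reps
    thermo_truth: pd.DataFrame      # site, residue, dH_true, dS_true
    site_truth: pd.DataFrame        # site, fc_true, slope_true, label
    scale_name: str


def gen_hypothesis_study(sites_exposed: dict[int, float] | None = None,
                         sites_buried: dict[int, float] | None = None,
                         mutant_residues: tuple[str, ...] = ("L", "V", "A", "T", "H"),
                         slope_magnitude: float = 15.0,
                         dH_center: float = -90.0,
                         t_half_C: float = 12.5,
                         scale_name: str = "hessa",
                         n_replicates: int = 3,
                         footprint_noise_cv: float = 0.0,
                         current_noise_sd: float = 0.0,
                         temp_grid_C: tuple[float, ...] = tuple(
                             float(t) for t in range(4, 21)),
                         i_max: float = 2000.0,
                         n_residues: int = 800,
                         seed: int = 0) -> HypothesisStudy:
    """Generate a study in which every site obeys the hypothesis.

    Exposed sites (FC > 1) receive a positive planted slope of dH
    against side-chain hydrophobicity, buried sites (FC < 1) a negative
    one; gating ramps for each mutant are generated from the implied dH,
    with dS set so every mutant half-activates at ``t_half_C`` (keeping
    the whole ramp inside the fittable Po window).  Run the footprinting
    and thermodynamics stages on the outputs and the consistency
    proportion is 1 at every slope threshold by construction.
    """
    from .hydrophobicity_scan import HydrophobicityScale

    if sites_exposed is None:
        sites_exposed = {137: 1.25, 263: 1.35, 390: 1.45}
    if sites_buried is None:
        sites_buried = {520: 0.80, 651: 0.72, 777: 0.64}
    overlap = set(sites_exposed) & set(sites_buried)
    if overlap:
        raise ConfigError(f"sites listed as both exposed and buried: {overlap}")
    scale = HydrophobicityScale.from_name(scale_name)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2)
    fp_seed = int(child[0].generate_state(1)[0] % 2 ** 31)

    fc_planted = {**sites_exposed, **sites_buried}
    fp_cfg = FootprintSimConfig(
        n_residues=n_residues,
        sites_exposed=tuple(sites_exposed),
        sites_buried=tuple(sites_buried),
        fc_planted=fc_planted,
        n_replicates=n_replicates,
        noise_cv=footprint_noise_cv,
        seed=fp_seed)
    footprint = gen_footprint_dataset(fp_cfg)

    sch = np.array([scale[r] for r in mutant_residues])
    sch_center = float(sch.mean())
    t_half_K = float(celsius_to_kelvin(t_half_C))

    gating: dict[tuple[int, str], list[CurrentTrace]] = {}
    thermo_rows = []
    site_rows = []
    trace_seeds = child[1].spawn(len(fc_planted) * len(mutant_residues))
    k = 0
    for site, fc in sorted(fc_planted.items()):
        slope = slope_magnitude if fc > 1 else -slope_magnitude
        for res in mutant_residues:
            dH = dH_center + slope * (scale[res] - sch_center)
            dS = dH / t_half_K
            reps = []
            for rep in range(n_replicates):
                seed_r = int(trace_seeds[k].generate_state(1)[0] % 2 ** 31) + rep
                cfg = GatingSimConfig(dH=dH, dS=dS, temp_grid_C=temp_grid_C,
                                      i_max=i_max, noise_sd=current_noise_sd,
                                      seed=seed_r)
                reps.append(gen_current_ramp(cfg))
            k += 1
            gating[(site, res)] = reps
            thermo_rows.append({"site": site, "residue": res,
                                "dH_true": dH, "dS_true": dS})
        site_rows.append({"site": site, "fc_true": fc, "slope_true": slope,
                          "label": ("more_exposed" if fc > 1 else "more_buried")})
    return HypothesisStudy(
        footprint=footprint,
        gating=gating,
        thermo_truth=pd.DataFrame(thermo_rows),
        site_truth=pd.DataFrame(site_rows),
        scale_name=scale_name)
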