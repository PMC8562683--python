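"""Forward simulator for the single-cell m6A imaging experiment.

Generates ground-truthed synthetic inputs for every downstream stage:

* TIRF fields of view (FOVs) containing diffraction-limited spots rendered
  as pixel-integrated 2D Gaussians with Poisson shot noise and Gaussian
  read noise (the standard CCD model),
* low-magnification nanowell scans with fluorescently stained cells of two
  or more phenotypes sitting in a regular well grid,
* per-molecule modification status expressed as a second colour channel,
* fiducial beads persistent across detection/hybridization rounds (with
  per-round stage offsets recorded in the ground truth),
* sequential hybridization (seqFISH) rounds, one gene per round.

Every quantity the analysis pipeline is supposed to recover (cell
occupancy, phenotypes, per-well molecule counts, planted m6A fractions,
round offsets, the RDM->COM registration offset) is recorded in a
:class:`GroundTruth` so round-trip tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "NoiseModel",
    "Phenotype",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "render_fov",
    "simulate_nanowell_scan",
    "simulate_experiment",
]

#: Channel naming used throughout: nanowell scans carry "nuclear" plus one
#: dye channel per phenotype; FOVs carry "polyA" (Cy3, every captured
#: molecule), "m6a" (antibody channel), "beads" (fiducials) and, in seqFISH
#: rounds, "readout".
POLYA_CHANNEL = "polyA"
M6A_CHANNEL = "m6a"
BEAD_CHANNEL = "beads"
READOUT_CHANNEL = "readout"


@dataclass(frozen=True)
class NoiseModel:
    """Additive-background CCD noise: Poisson shot noise then Gaussian read noise.

    ``shot_noise=False`` disables the Poisson stage (and a zero
    ``read_noise_sd`` the Gaussian stage), yielding a deterministic
    noise-free rendering for round-trip tests.
    """

    background_level: float = 100.0
    photon_gain: float = 1.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.photon_gain <= 0:
            raise ValueError("photon_gain must be > 0")


NOISELESS = NoiseModel(background_level=0.0, photon_gain=1.0,
                       read_noise_sd=0.0, shot_noise=False)


@dataclass(frozen=True)
class Phenotype:
    """A simulated cell type.

    ``channel_intensities`` maps dye channel name -> blob intensity in the
    nanowell scan; ``mean_molecules`` is the Poisson mean of captured polyA+
    molecules per cell; ``m6a_fraction`` the probability a molecule is
    m6A-modified; ``expression`` the per-gene mixture weights.
    """

    name: str
    channel_intensities: dict[str, float]
    mean_molecules: float = 200.0
    m6a_fraction: float = 0.3
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.m6a_fraction <= 1.0:
            raise ValueError("m6a_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Geometry and statistical parameters of a simulated experiment.

    Defaults follow the physical device: a 121x381 nanowell occupancy grid
    of which a 31x51 block of wells is imaged as TIRF FOVs.  Both shapes are
    free parameters so tests can run on small instances.
    """

    com_shape: tuple[int, int] = (121, 381)
    rdm_shape: tuple[int, int] = (31, 51)
    rdm_offset: tuple[int, int] = (0, 0)  # planted COM position of the FOV block
    well_pitch_px: float = 12.0           # nanowell scan pixels per well
    fov_shape: tuple[int, int] = (80, 80)
    fov_margin: int = 6                   # blank frame around each dense square
    loading_rate: float = 0.6             # mean cells per well (Poisson)
    phenotypes: tuple[Phenotype, ...] = ()
    mixture: tuple[float, ...] = ()       # phenotype weights; default uniform
    psf_sigma: float = 1.3
    spot_amplitude_median: float = 150.0  # log-normal median of spot peak height
    spot_amplitude_sigma: float = 0.35    # log-normal shape
    min_spot_separation: float = 4.0
    n_beads_per_fov: int = 4
    bead_amplitude_factor: float = 10.0
    round_gene_map: dict[int, str] = field(default_factory=dict)
    round_offsets: dict[int, tuple[float, float]] = field(default_factory=dict)
    noise: NoiseModel = NoiseModel()
    cell_blob_sigma: float = 2.0
    nuclear_intensity: float = 300.0

    def __post_init__(self) -> None:
        if not self.phenotypes:
            self.phenotypes = (
                Phenotype("K562", {"green": 250.0, "red": 30.0},
                          mean_molecules=200.0, m6a_fraction=0.30),
                Phenotype("YAC1", {"green": 30.0, "red": 250.0},
                          mean_molecules=100.0, m6a_fraction=0.15),
            )
        if not self.mixture:
            self.mixture = tuple(1.0 / len(self.phenotypes) for _ in self.phenotypes)
        self.validate()

    @property
    def genes(self) -> list[str]:
        g: list[str] = []
        for p in self.phenotypes:
            for name in p.expression:
                if name not in g:
                    g.append(name)
        return g

    @property
    def dye_channels(self) -> list[str]:
        ch: list[str] = []
        for p in self.phenotypes:
            for c in p.channel_intensities:
                if c not in ch:
                    ch.append(c)
        return ch

    def validate(self) -> None:
        errors: list[str] = []
        if min(self.com_shape) <= 0 or min(self.rdm_shape) <= 0:
            errors.append("grid shapes must be positive")
        if not (self.rdm_shape[0] < self.com_shape[0]
                and self.rdm_shape[1] < self.com_shape[1]):
            errors.append("RDM shape must be strictly smaller than COM shape")
        orow, ocol = self.rdm_offset
        if not (0 <= orow <= self.com_shape[0] - self.rdm_shape[0]
                and 0 <= ocol <= self.com_shape[1] - self.rdm_shape[1]):
            errors.append("rdm_offset places the FOV block outside the COM")
        if self.well_pitch_px < 4.0:
            errors.append("well_pitch_px too small to separate wells (need >= 4)")
        if len(self.mixture) != len(self.phenotypes):
            errors.append("mixture length must equal number of phenotypes")
        genes = self.genes
        for rnd, gene in self.round_gene_map.items():
            if gene not in genes:
                errors.append(
                    f"round {rnd} maps to gene {gene!r} absent from every "
                    "phenotype expression model"
                )
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, recorded at generation time.

    ``wells`` has one row per cell (well_row, well_col, phenotype and one
    column per dye channel); ``well_molecules`` one row per occupied-block
    well with total / m6a / per-gene molecule counts; ``spot_truth`` one row
    per planted molecule (fov, round, channel, true centre, gene, modified);
    ``beads`` the per-FOV fiducial positions in round-0 coordinates.
    """

    wells: pd.DataFrame
    well_molecules: pd.DataFrame
    spot_truth: pd.DataFrame
    beads: pd.DataFrame
    rdm_offset: tuple[int, int]
    round_offsets: dict[int, tuple[float, float]]
    m6a_fractions: dict[str, float]
    seed: int | None

    def occupancy(self, shape: tuple[int, int]) -> np.ndarray:
        com = np.zeros(shape, dtype=int)
        if len(self.wells):
            np.add.at(com, (self.wells.well_row.to_numpy(),
                            self.wells.well_col.to_numpy()), 1)
        return com


@dataclass
class SimulatedExperiment:
    """Simulator output bundle: ground truth, nanowell scan, FOV stacks."""

    truth: GroundTruth
    nanowell_scan: dict[str, np.ndarray]        # channel -> 2D image
    scan_origin: tuple[float, float]            # pixel centre of well (0, 0)
    well_pitch_px: float
    fovs: dict[tuple[int, int], dict[int, dict[str, np.ndarray]]]
    # fovs[(fov_row, fov_col)][round][channel] -> 2D image
    config: SimulationConfig


def _integrated_gaussian(shape, centers, amplitudes, sigma):
    """Sum of 2D Gaussians integrated over pixel areas (amplitude = peak height)."""
    img = np.zeros(shape, dtype=float)
    if len(centers) == 0:
        return img
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    s2 = sigma * np.sqrt(2.0)
    norm = 2.0 * np.pi * sigma**2  # converts peak amplitude to integrated photons
    for (r0, c0), amp in zip(centers, amplitudes):
        # pixel-integrated profile via erf differences, separable
        fr = 0.5 * (special.erf((rows - r0 + 0.5) / s2)
                    - special.erf((rows - r0 - 0.5) / s2))
        fc = 0.5 * (special.erf((cols - c0 + 0.5) / s2)
                    - special.erf((cols - c0 - 0.5) / s2))
        img += amp * norm * np.outer(fr, fc)
    return img


def render_fov(
    spot_truth,
    psf_sigma: float,
    shape: tuple[int, int],
    noise: NoiseModel = NOISELESS,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render one field of view from a list of (centre, amplitude) spots.

    ``spot_truth`` is an iterable of ((row, col), amplitude) pairs (an
    optional third channel element is ignored here; callers split channels
    before rendering).  The expected image is ``background + sum of
    pixel-integrated Gaussians``; Poisson shot noise is applied to the
    photon image and Gaussian read noise added afterwards.
    """
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive (rows, cols)")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    centers, amps = [], []
    for item in spot_truth:
        (r, c), amp = item[0], item[1]
        if not (-0.5 <= r <= shape[0] - 0.5 and -0.5 <= c <= shape[1] - 0.5):
            raise ValueError(f"spot centre ({r}, {c}) outside image {shape}")
        centers.append((float(r), float(c)))
        amps.append(float(amp))
    expected = noise.background_level + _integrated_gaussian(shape, centers, amps,
                                                             psf_sigma)
    if not noise.shot_noise and noise.read_noise_sd == 0.0:
        return expected
    rng = np.random.default_rng(seed)
    img = expected
    if noise.shot_noise:
        img = rng.poisson(expected / noise.photon_gain) * noise.photon_gain
    if noise.read_noise_sd > 0.0:
        img = img + rng.normal(0.0, noise.read_noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def _place_spots(rng, n, lo_r, hi_r, lo_c, hi_c, min_sep, max_tries=40):
    """Uniform positions in a box with best-effort minimum separation."""
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        for _ in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in pts):
                pts.append((r, c))
                break
        else:
            pts.append((rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)))
    return pts


def simulate_nanowell_scan(
    wells: pd.DataFrame,
    grid: tuple[int, int],
    well_pitch: float,
    dye_channels: list[str],
    *,
    cell_blob_sigma: float = 2.0,
    nuclear_intensity: float = 300.0,
    noise: NoiseModel = NoiseModel(background_level=20.0, read_noise_sd=3.0),
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], tuple[float, float]]:
    """Render a low-magnification scan of the nanowell grid.

    ``wells`` has one row per cell with columns ``well_row``, ``well_col``
    and one intensity column per dye channel.  Each cell appears as a
    Gaussian blob at its well centre (small intra-well jitter) in the
    nuclear channel and in its dye channels.  Returns the per-channel image
    dict and the scan origin (pixel coordinates of well (0, 0) centre).
    """
    if well_pitch < 4.0:
        raise ValueError("well pitch too small to separate wells (need >= 4 px)")
    rng = np.random.default_rng(seed)
    nrow, ncol = grid
    margin = well_pitch  # half-well border
    shape = (int(round(nrow * well_pitch + 2 * margin)),
             int(round(ncol * well_pitch + 2 * margin)))
    origin = (margin + well_pitch / 2.0, margin + well_pitch / 2.0)
    channels = ["nuclear"] + list(dye_channels)
    images = {}
    centers: list[tuple[float, float]] = []
    # cells sit anywhere in the well interior (uniform), as on the real array
    jitter = 0.30 * well_pitch
    rows = wells.well_row.to_numpy() if len(wells) else np.empty(0, int)
    cols = wells.well_col.to_numpy() if len(wells) else np.empty(0, int)
    for r, c in zip(rows, cols):
        centers.append((origin[0] + r * well_pitch + rng.uniform(-jitter, jitter),
                        origin[1] + c * well_pitch + rng.uniform(-jitter, jitter)))
    for ch in channels:
        if ch == "nuclear":
            amps = [nuclear_intensity] * len(centers)
        else:
            amps = (wells[ch].to_numpy(float).tolist()
                    if ch in wells.columns and len(wells) else [0.0] * len(centers))
        img = noise.background_level + _integrated_gaussian(shape, centers, amps,
                                                            cell_blob_sigma)
        if noise.shot_noise:
            img = rng.poisson(img).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0, noise.read_noise_sd, size=shape)
        images[ch] = np.clip(img, 0, None)
    return images, origin


def simulate_experiment(config: SimulationConfig,
                        seed: int | None = None) -> SimulatedExperiment:
    """Simulate a full nanowell + flow-cell experiment.

    The COM block at ``config.rdm_offset`` of shape ``rdm_shape`` is the
    imaged region: each of its wells maps to one TIRF FOV whose interior
    square (inside ``fov_margin``) carries the well's captured molecules —
    the grid-of-dense-squares appearance of the real flow cell.  Round 0 is
    the polyA/m6A detection round; rounds 1..R are seqFISH readout rounds,
    one gene each, shifted by the per-round stage offsets.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    nrow, ncol = config.com_shape
    frow, fcol = config.rdm_shape
    orow, ocol = config.rdm_offset
    phenos = config.phenotypes
    weights = np.asarray(config.mixture, float)
    weights = weights / weights.sum()

    # --- cell loading over the whole COM grid ---
    n_cells = rng.poisson(config.loading_rate, size=(nrow, ncol))
    cell_rows = []
    for (r, c), k in np.ndenumerate(n_cells):
        for _ in range(int(k)):
            p = phenos[rng.choice(len(phenos), p=weights)]
            row = {"well_row": r, "well_col": c, "phenotype": p.name}
            for ch in config.dye_channels:
                base = p.channel_intensities.get(ch, 20.0)
                row[ch] = max(0.0, base * rng.lognormal(0.0, 0.15))
            cell_rows.append(row)
    wells = pd.DataFrame(cell_rows,
                         columns=["well_row", "well_col", "phenotype",
                                  *config.dye_channels])

    # --- nanowell scan ---
    scan, origin = simulate_nanowell_scan(
        wells, config.com_shape, config.well_pitch_px, config.dye_channels,
        cell_blob_sigma=config.cell_blob_sigma,
        nuclear_intensity=config.nuclear_intensity,
        seed=rng,
    )

    # --- molecules per imaged well ---
    genes = config.genes
    mol_rows, spot_rows, bead_rows = [], [], []
    fovs: dict[tuple[int, int], dict[int, dict[str, np.ndarray]]] = {}
    amp_mu = np.log(config.spot_amplitude_median)
    interior = (config.fov_margin, config.fov_shape[0] - config.fov_margin,
                config.fov_margin, config.fov_shape[1] - config.fov_margin)
    rounds = [0] + sorted(config.round_gene_map)
    round_offsets = {0: (0.0, 0.0)}
    for rnd in sorted(config.round_gene_map):
        round_offsets[rnd] = config.round_offsets.get(
            rnd, (float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2))))

    for fr in range(frow):
        for fc in range(fcol):
            wr, wc = orow + fr, ocol + fc
            cells_here = wells[(wells.well_row == wr) & (wells.well_col == wc)]
            mol_count = 0
            mol_gene, mol_mod = [], []
            for _, cell in cells_here.iterrows():
                p = next(ph for ph in phenos if ph.name == cell.phenotype)
                k = int(rng.poisson(p.mean_molecules))
                mol_count += k
                if genes and p.expression:
                    w = np.array([p.expression.get(g, 0.0) for g in genes], float)
                    w = w / w.sum() if w.sum() > 0 else np.full(len(genes),
                                                               1.0 / len(genes))
                    mol_gene.extend(rng.choice(genes, size=k, p=w).tolist())
                else:
                    mol_gene.extend([""] * k)
                mol_mod.extend((rng.random(k) < p.m6a_fraction).tolist())
            pts = _place_spots(rng, mol_count, *interior,
                               min_sep=config.min_spot_separation)
            amps = rng.lognormal(amp_mu, config.spot_amplitude_sigma,
                                 size=mol_count)
            gene_counts = {g: 0 for g in genes}
            gene_mod_counts = {g: 0 for g in genes}
            for g, m in zip(mol_gene, mol_mod):
                if g:
                    gene_counts[g] += 1
                    if m:
                        gene_mod_counts[g] += 1
            mol_rows.append({
                "well_row": wr, "well_col": wc, "fov_row": fr, "fov_col": fc,
                "n_cells": len(cells_here), "total": mol_count,
                "m6a": int(np.sum(mol_mod)),
                **{f"n_{g}": gene_counts[g] for g in genes},
                **{f"m6a_{g}": gene_mod_counts[g] for g in genes},
            })
            # fiducial beads, constant across rounds in stage coordinates
            beads = _place_spots(rng, config.n_beads_per_fov, *interior,
                                 min_sep=2 * config.min_spot_separation)
            bead_amp = config.bead_amplitude_factor * config.spot_amplitude_median
            for br, bc in beads:
                bead_rows.append({"fov_row": fr, "fov_col": fc,
                                  "row": br, "col": bc})

            per_round: dict[int, dict[str, np.ndarray]] = {}
            for rnd in rounds:
                drow, dcol = round_offsets[rnd]
                chans: dict[str, list[tuple[tuple[float, float], float]]] = {}
                if rnd == 0:
                    chans[POLYA_CHANNEL] = [((r, c), a)
                                            for (r, c), a in zip(pts, amps)]
                    chans[M6A_CHANNEL] = [
                        ((r + rng.normal(0, 0.1), c + rng.normal(0, 0.1)), a)
                        for (r, c), a, m in zip(pts, amps, mol_mod) if m
                    ]
                else:
                    gene = config.round_gene_map[rnd]
                    chans[READOUT_CHANNEL] = [
                        ((r + drow, c + dcol), a)
                        for (r, c), a, g in zip(pts, amps, mol_gene) if g == gene
                    ]
                chans[BEAD_CHANNEL] = [((br + drow, bc + dcol), bead_amp)
                                       for br, bc in beads]
                imgs: dict[str, np.ndarray] = {}
                for ch, truth_list in chans.items():
                    truth_list = [t for t in truth_list
                                  if -0.5 <= t[0][0] <= config.fov_shape[0] - 0.5
                                  and -0.5 <= t[0][1] <= config.fov_shape[1] - 0.5]
                    imgs[ch] = render_fov(truth_list, config.psf_sigma,
                                          config.fov_shape, config.noise,
                                          seed=rng)
                    for (r, c), a in truth_list:
                        spot_rows.append({
                            "fov_row": fr, "fov_col": fc, "round": rnd,
                            "channel": ch, "row": r, "col": c, "amplitude": a,
                        })
                per_round[rnd] = imgs
            fovs[(fr, fc)] = per_round

    gene_cols = [f"n_{g}" for g in genes] + [f"m6a_{g}" for g in genes]
    truth = GroundTruth(
        wells=wells,
        well_molecules=pd.DataFrame(
            mol_rows, columns=["well_row", "well_col", "fov_row", "fov_col",
                               "n_cells", "total", "m6a", *gene_cols]),
        spot_truth=pd.DataFrame(
            spot_rows, columns=["fov_row", "fov_col", "round", "channel",
                                "row", "col", "amplitude"]),
        beads=pd.DataFrame(bead_rows,
                           columns=["fov_row", "fov_col", "row", "col"]),
        rdm_offset=(orow, ocol),
        round_offsets=round_offsets,
        m6a_fractions={p.name: p.m6a_fraction for p in phenos},
        seed=seed,
    )
    return SimulatedExperiment(truth=truth, nanowell_scan=scan,
                               scan_origin=origin,
                               well_pitch_px=config.well_pitch_px,
                               fovs=fovs, config=config)
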