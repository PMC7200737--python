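"""Seeded synthetic-data generators for every pipeline input.

Each generator emits both the data object and a machine-readable truth
record so that parameter-recovery tests consume only generated artifacts.
All randomness is Gaussian (thermal NMR noise model) and flows from an
explicit integer seed; the same seed reproduces byte-identical output.

Presets mirror the experimental conditions the analysis targets: the TROSY
acquisition grid (120 x 1024 complex points, 24/42 ms acquisition, SNR ~10),
the 6 ligands x 31 observables rank-2 table, and the measurement relaxation
delay grids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hbonds import EnsembleModel, Model, Residue, place_amide_protons
from .lineshape import (DecaySeries, FidGrid, GridSpec, ProcessingScheme,
                        Resonance2D, process_spectrum, synthesize_fid)

logger = logging.getLogger("gpcrdyn")

#: relaxation-delay presets (s): R1 and R2 grids at 14.1 T / 21.2 T
MEASUREMENT_DELAYS = {
    "R1_14T": (0.020, 2.004),
    "R1_21T": (0.020, 3.004),
    "R2_14T": (0.002, 0.006, 0.012),
    "R2_21T": (0.002, 0.006, 0.010),
}

DEFAULT_SNR = 10.0


# ---------------------------------------------------------------------------
# FID datasets
# ---------------------------------------------------------------------------

def gen_fid_dataset(peaks: Sequence[Resonance2D],
                    grid: GridSpec | None = None,
                    snr: float = DEFAULT_SNR,
                    seed: int = 0,
                    scheme: ProcessingScheme = ProcessingScheme()
                    ) -> tuple:
    """Noisy FID plus ground-truth table at a target spectral SNR.

    SNR follows the spectrometer-software convention (Bruker SINO): tallest
    peak height of the processed spectrum over twice the rms baseline noise
    of its real part.  The time-domain noise rms required to hit the target
    is calibrated empirically by processing a unit-rms pure-noise grid drawn
    from the same seed stream.  Returns
    (FidGrid, truth DataFrame, time-domain noise rms).
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    grid = grid or GridSpec.trosy_grid()
    rng = np.random.default_rng(seed)

    clean = synthesize_fid(peaks, grid)
    height = float(np.abs(process_spectrum(clean, scheme).data).max())
    probe = synthesize_fid([], grid, noise_rms=1.0, rng=rng)
    noise_gain = float(np.sqrt(
        np.mean(process_spectrum(probe, scheme).data.real ** 2)))
    noise_rms = height / (snr * 2.0 * noise_gain)

    fid = synthesize_fid(peaks, grid, noise_rms=noise_rms, rng=rng)
    truth = pd.DataFrame(
        [{"peak": i, "amplitude": p.amplitude, "freq1": p.freq1,
          "freq2": p.freq2, "r2_1": p.r2_1, "r2_2": p.r2_2}
         for i, p in enumerate(peaks)])
    return fid, truth, noise_rms


# ---------------------------------------------------------------------------
# Rank-2 ligand x observable tables
# ---------------------------------------------------------------------------

#: latent score centers for the three pharmacology-like groups
GROUP_CENTERS = {"agonist": (2.5, 1.0), "antagonist": (-2.0, 1.5),
                 "inverse_agonist": (0.0, -2.5)}


def gen_two_factor_table(n_ligands: int = 6, n_vars: int = 31,
                         loadings: np.ndarray | None = None,
                         noise_sd: float = 0.0, seed: int = 0) -> tuple:
    """Ligands x observables matrix with latent rank-2 structure.

    X = mean + scores @ loadings.T + noise.  Scores are drawn around three
    group centers emulating agonist / antagonist / inverse-agonist
    pharmacology (the 6-ligand default assigns 2/3/1 ligands per group, as
    in a typical orthosteric ligand panel).  Returns (ObservationMatrix,
    truth dict with scores, loadings, labels).
    """
    from .conformers import ObservationMatrix

    rng = np.random.default_rng(seed)
    if loadings is None:
        raw = rng.normal(size=(n_vars, 2))
        q, _ = np.linalg.qr(raw)
        loadings = q[:, :2] * math.sqrt(n_vars / 2.0)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (n_vars, 2):
        raise ValueError(f"loadings must be ({n_vars}, 2)")

    group_names = list(GROUP_CENTERS)
    counts = [max(1, n_ligands // 3)] * 3
    counts[1] += n_ligands - sum(counts)
    labels, centers = [], []
    for name, cnt in zip(group_names, counts):
        labels += [name] * cnt
        centers += [GROUP_CENTERS[name]] * cnt
    scores = np.asarray(centers, dtype=float) \
        + rng.normal(0.0, 0.3, size=(n_ligands, 2))
    x = scores @ loadings.T
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    index = pd.Index([f"ligand_{i + 1}" for i in range(n_ligands)],
                     name="ligand")
    columns = [f"var_{j + 1}" for j in range(n_vars)]
    df = pd.DataFrame(x, index=index, columns=columns)
    matrix = ObservationMatrix(data=df,
                               labels=pd.Series(labels, index=index,
                                                name="pharm_class"))
    truth = {"scores": scores, "loadings": loadings, "labels": labels}
    return matrix, truth


# ---------------------------------------------------------------------------
# Relaxation decay series
# ---------------------------------------------------------------------------

def gen_relaxation_series(rate: float, delays: Sequence[float],
                          noise_frac: float = 0.0, seed: int = 0,
                          amplitude: float = 1.0) -> DecaySeries:
    """Exponential decay A exp(-R t) (1 + eps) with fractional noise."""
    if rate <= 0:
        raise ValueError("rate must be > 0 s^-1")
    t = np.asarray(delays, dtype=float)
    a = amplitude * np.exp(-rate * t)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + rng.normal(0.0, noise_frac, size=t.shape))
    errors = np.abs(amplitude * np.exp(-rate * t)) * noise_frac \
        if noise_frac > 0 else None
    return DecaySeries(delays=t, amplitudes=a, errors=errors)


# ---------------------------------------------------------------------------
# Ideal backbones and coordinate ensembles
# ---------------------------------------------------------------------------

#: (phi, psi) in degrees for the supported backbone kinds
BACKBONE_DIHEDRALS = {"alpha": (-57.0, -47.0),
                      "three_ten": (-49.0, -26.0),
                      "extended": (180.0, 180.0)}

# standard backbone covalent geometry (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_OMEGA = 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(n_res: int, kind: str = "alpha",
                      chain: str = "A") -> EnsembleModel:
    """Single-model poly-alanine-like backbone from standard dihedrals.

    kind selects (phi, psi): alpha (-57, -47), three_ten (-49, -26) or
    extended (180, 180).  Backbone N, CA, C, O atoms are built with
    standard bond geometry; carbonyl O lies in the peptide plane, anti to
    the following N.  Amide protons are placed with the same convention as
    the analysis (1.02 Angstrom, anti to the preceding carbonyl).
    """
    if n_res < 8:
        raise ValueError("need n_res >= 8 for meaningful H-bond geometry")
    if kind not in BACKBONE_DIHEDRALS:
        raise ValueError(f"kind must be one of {sorted(BACKBONE_DIHEDRALS)}")
    phi, psi = BACKBONE_DIHEDRALS[kind]

    # seed triad for residue 1 (arbitrary rigid placement)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    c0 = _nerf(n0 + np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CA_C,
               _A_N_CA_C, 60.0)

    coords = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        prev = coords[-1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N,
                    _A_CA_C_N, psi)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _B_N_CA,
                     _A_C_N_CA, _OMEGA)
        c_i = _nerf(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O in the peptide plane, anti to the next N
    for i, res in enumerate(coords):
        if i + 1 < n_res:
            res["O"] = _nerf(coords[i + 1]["N"], res["CA"], res["C"],
                             _B_C_O, 120.8, 180.0)
        else:  # C-terminal O: anti to N-CA within the residue plane
            res["O"] = _nerf(res["N"], res["CA"], res["C"], _B_C_O,
                             120.8, 180.0)

    residues = {i + 1: Residue(seqid=i + 1, name="ALA",
                               atoms={k: v.copy() for k, v in res.items()})
                for i, res in enumerate(coords)}
    model = Model(chains={chain: residues})
    place_amide_protons(model)
    return EnsembleModel(models=[model], name=f"ideal_{kind}")


def gen_ensemble(base: EnsembleModel, n_models: int,
                 jitter_sd: float = 0.0, seed: int = 0) -> EnsembleModel:
    """Ensemble of jittered copies of a base model.

    Each of n_models copies of the first base model receives independent
    Gaussian displacement of SD jitter_sd (Angstrom) on every coordinate,
    emulating the coordinate spread of an ensemble refinement.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    template = base.models[0]
    models = []
    for _ in range(n_models):
        chains = {}
        for ch, residues in template.chains.items():
            chains[ch] = {
                seqid: Residue(
                    seqid=res.seqid, name=res.name, icode=res.icode,
                    atoms={a: pos + rng.normal(0.0, jitter_sd, 3)
                           for a, pos in res.atoms.items()})
                for seqid, res in residues.items()}
        models.append(Model(chains=chains))
    return EnsembleModel(models=models, name=base.name + "_ensemble")
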