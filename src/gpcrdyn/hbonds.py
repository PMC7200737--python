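"""Backbone amide H-bond geometry across structural ensembles.

Helical backbones are distinguished by which carbonyl accepts the amide
proton of residue i: the alpha-helical H-bond goes to O of residue i-4, the
3_10-helical one to O of residue i-3.  For each residue the Euclidean
distances d(H_i...O_{i-3}) and d(H_i...O_{i-4}) are evaluated per ensemble
model, averaged per chain, and a bond is called broken when the mean
distance exceeds a threshold (default 3.0 Angstrom, strict inequality).

Crystal structures usually lack amide protons; when absent they are placed
at 1.02 Angstrom from N (matching the N-H length of the relaxation model),
in the C(i-1)-N-CA plane, anti to the preceding carbonyl C=O direction.
Native H atoms, when present, are kept untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("gpcrdyn")

BROKEN_THRESHOLD = 3.0  # Angstrom
N_H_LENGTH = 1.02       # Angstrom, matches the relaxation-model r_NH

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue's backbone atom coordinates (Angstrom)."""

    seqid: int
    name: str
    atoms: dict  # atom name -> np.ndarray(3)
    icode: str = " "

    def has(self, *names: str) -> bool:
        return all(n in self.atoms for n in names)


@dataclass
class Model:
    """chains: chain id -> {seqid: Residue}."""

    chains: dict


@dataclass
class EnsembleModel:
    """Multi-model ensemble with shared topology."""

    models: list           # list[Model]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        topo = {ch: sorted(res) for ch, res in self.models[0].chains.items()}
        for k, m in enumerate(self.models[1:], start=2):
            if {ch: sorted(res) for ch, res in m.chains.items()} != topo:
                raise ValueError(f"model {k} topology differs from model 1")


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_ensemble(pdb_source: str) -> EnsembleModel:
    """Read a (multi-MODEL) PDB file into an EnsembleModel.

    Alternate locations are resolved to the conformer gemmi retains after
    removing alternative conformations (the highest-occupancy one per its
    sorting); insertion codes are preserved in the residue record; residues
    missing all of N/CA are dropped with a warning.
    """
    st = gemmi.read_structure(str(pdb_source))
    st.setup_entities()
    st.remove_alternative_conformations()
    models = []
    for gm in st:
        chains: dict = {}
        for gch in gm:
            residues: dict = {}
            for gres in gch:
                atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                         for a in gres if a.name in BACKBONE + ("H", "HN")}
                if "HN" in atoms and "H" not in atoms:
                    atoms["H"] = atoms.pop("HN")
                res = Residue(seqid=gres.seqid.num, name=gres.name,
                              atoms=atoms,
                              icode=gres.seqid.icode or " ")
                if not res.has("N", "CA"):
                    logger.warning("chain %s residue %d %s lacks backbone "
                                   "N/CA; excluded", gch.name, res.seqid,
                                   res.name)
                    continue
                residues[res.seqid] = res
            if residues:
                chains[gch.name] = residues
        models.append(Model(chains=chains))
    return EnsembleModel(models=models, name=st.name)


def write_ensemble(ensemble: EnsembleModel, path: str) -> None:
    """Write the ensemble as a multi-MODEL PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = ensemble.name or "ensemble"
    for k, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(k)
        for ch_name, residues in model.chains.items():
            gch = gemmi.Chain(ch_name)
            for seqid in sorted(residues):
                res = residues[seqid]
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(seqid, res.icode)
                for aname, pos in res.atoms.items():
                    atom = gemmi.Atom()
                    atom.name = aname
                    atom.element = gemmi.Element(aname[0])
                    atom.pos = gemmi.Position(*map(float, pos))
                    atom.occ = 1.0
                    gres.add_atom(atom)
                gch.add_residue(gres)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# Proton placement and distances
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def place_amide_protons(model: Model) -> Model:
    """Place missing backbone amide protons.

    H is put N_H_LENGTH from N, within the C(i-1)-N-CA plane, anti to the
    C(i-1)=O carbonyl direction.  Chain N-termini, prolines and residues
    whose predecessor (by sequence number) is absent are skipped.  Existing
    H atoms are kept.
    """
    for residues in model.chains.values():
        for seqid, res in residues.items():
            if "H" in res.atoms or res.name == "PRO":
                continue
            prev = residues.get(seqid - 1)
            if prev is None or not prev.has("C", "O") or not res.has("N", "CA"):
                continue
            n_pos, ca = res.atoms["N"], res.atoms["CA"]
            c_prev, o_prev = prev.atoms["C"], prev.atoms["O"]
            anti_co = _unit(c_prev - o_prev)
            normal = _unit(np.cross(c_prev - n_pos, ca - n_pos))
            in_plane = anti_co - np.dot(anti_co, normal) * normal
            res.atoms["H"] = n_pos + N_H_LENGTH * _unit(in_plane)
    return model


def _parse_selection(selection: str | None, model: Model) -> dict:
    """'chain:start-end' -> {chain: (start, end)}; None selects everything."""
    if selection is None:
        return {ch: (-10 ** 9, 10 ** 9) for ch in model.chains}
    out = {}
    for part in selection.split(","):
        chain, _, rng = part.strip().partition(":")
        if chain not in model.chains:
            raise ValueError(f"selection chain {chain!r} not in model "
                             f"(chains: {sorted(model.chains)})")
        if rng:
            lo, _, hi = rng.partition("-")
            out[chain] = (int(lo), int(hi or lo))
        else:
            out[chain] = (-10 ** 9, 10 ** 9)
    return out


def hbond_distances(model: Model, selection: str | None = None
                    ) -> pd.DataFrame:
    """Per-residue d(H_i...O_{i-3}) and d(H_i...O_{i-4}) in Angstrom.

    Acceptors are located by residue sequence number, so chain gaps yield
    missing values (NaN) rather than distances to the wrong residue.
    Residues without an H (chain starts, prolines) are absent from the
    output.
    """
    sel = _parse_selection(selection, model)
    rows = []
    for chain, (lo, hi) in sel.items():
        residues = model.chains[chain]
        for seqid in sorted(residues):
            if not lo <= seqid <= hi:
                continue
            res = residues[seqid]
            if "H" not in res.atoms:
                continue
            h = res.atoms["H"]
            dist = {}
            for offset, col in ((3, "d_HO_i3"), (4, "d_HO_i4")):
                acceptor = residues.get(seqid - offset)
                dist[col] = (float(np.linalg.norm(h - acceptor.atoms["O"]))
                             if acceptor is not None and "O" in acceptor.atoms
                             else np.nan)
            rows.append({"chain": chain, "resid": seqid, **dist})
    return pd.DataFrame(rows, columns=["chain", "resid", "d_HO_i3",
                                       "d_HO_i4"])


def ensemble_stats(ensemble: EnsembleModel, selection: str | None = None,
                   threshold: float = BROKEN_THRESHOLD,
                   place_protons: bool = True,
                   bw_map: dict | None = None) -> pd.DataFrame:
    """Per-chain, per-residue mean and SD of H...O distances over models.

    The broken flag is True when the closer of the two mean acceptor
    distances still exceeds the threshold (strict >), i.e. the amide is
    H-bonded to neither O_{i-3} nor O_{i-4}.  Single-model ensembles have
    SD 0.  An optional bw_map (resid -> Ballesteros-Weinstein label) is
    passed through to the output.
    """
    frames = []
    for k, model in enumerate(ensemble.models):
        if place_protons:
            place_amide_protons(model)
        frames.append(hbond_distances(model, selection).assign(model=k))
    allm = pd.concat(frames, ignore_index=True)
    grouped = allm.groupby(["chain", "resid"], sort=True)
    out = grouped.agg(
        mean_d3=("d_HO_i3", "mean"), sd_d3=("d_HO_i3", lambda s: _sd(s)),
        mean_d4=("d_HO_i4", "mean"), sd_d4=("d_HO_i4", lambda s: _sd(s)),
    ).reset_index()
    closest = out[["mean_d3", "mean_d4"]].min(axis=1)
    out["broken"] = closest.apply(
        lambda d: classify_broken(d, threshold) if np.isfinite(d) else True)
    out["bw"] = out["resid"].map(bw_map) if bw_map else None
    return out


def _sd(values: pd.Series) -> float:
    v = values.dropna()
    return float(v.std(ddof=0)) if len(v) else float("nan")


def classify_broken(d_ho: float, threshold: float = BROKEN_THRESHOLD) -> bool:
    """True when an H...O distance exceeds the threshold (strict >)."""
    if d_ho <= 0:
        raise ValueError("distance must be > 0 Angstrom")
    return d_ho > threshold


def classify_hbond_type(d3: float, d4: float,
                        threshold: float = BROKEN_THRESHOLD) -> str:
    """'alpha', 'three_ten' or 'broken' from the two acceptor distances."""
    if min(d3, d4) > threshold:
        return "broken"
    return "alpha" if d4 < d3 else "three_ten"
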