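"""File input/output for structures, trajectories, traces and cohorts.

PDB reading/writing is delegated to biotite; everything else is plain
delimited text (whitespace node tables, CSV traces with a JSON sidecar,
TSV cohorts, YAML panels) so all artifacts stay human-readable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .cohort import PanelVariant, VariantPanel
from .enm import CoarseStructure
from .ephys import RampTrace
from .ionbox import BONDI_RADII
from .pore import AtomicStructure, Trajectory

__all__ = [
    "load_structure_pdb",
    "load_trajectory_pdb",
    "save_trajectory_pdb",
    "coarse_grain",
    "load_node_table",
    "save_node_table",
    "load_trace",
    "save_trace",
    "load_cohort",
    "save_cohort",
    "load_panel",
    "save_panel",
]

logger = logging.getLogger(__name__)


def _vdw_for(elements: np.ndarray) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, element in enumerate(elements):
        key = str(element).upper()
        try:
            radii[i] = bst.info.vdw_radius_single(key)
        except (KeyError, ValueError):
            radii[i] = BONDI_RADII.get(key, 1.7)
    return radii


def _from_atom_array(array: bst.AtomArray) -> AtomicStructure:
    return AtomicStructure(
        atom_names=array.atom_name.astype(object),
        elements=array.element.astype(object),
        res_ids=array.res_id,
        chain_ids=array.chain_id.astype(object),
        coords=array.coord,
        vdw_radii=_vdw_for(array.element),
    )


def load_structure_pdb(path, model: int = 1) -> AtomicStructure:
    """Read one model of a PDB file (ATOM/HETATM records)."""
    pdb = bpdb.PDBFile.read(str(path))
    return _from_atom_array(pdb.get_structure(model=model))


def load_trajectory_pdb(path, frame_interval_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL) as a trajectory.

    PDB carries no time axis, so frame times are synthesized as
    ``frame_interval_ps`` times the frame index.
    """
    pdb = bpdb.PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    topology = _from_atom_array(stack[0])
    times = frame_interval_ps * np.arange(stack.stack_depth(), dtype=float)
    return Trajectory(topology, stack.coord, times)


def _to_atom_array(structure: AtomicStructure,
                   coords: np.ndarray) -> bst.AtomArray:
    n = structure.n_atoms
    array = bst.AtomArray(n)
    array.coord = np.asarray(coords, dtype=np.float32)
    array.chain_id = np.array([str(c)[:4] for c in structure.chain_ids])
    array.res_id = structure.res_ids
    array.res_name = np.array(["UNK"] * n)
    array.atom_name = np.array([str(a)[:4] for a in structure.atom_names])
    array.element = np.array([str(e) for e in structure.elements])
    array.hetero = np.array([True] * n)
    return array


def save_trajectory_pdb(trajectory: Trajectory, path) -> None:
    arrays = [_to_atom_array(trajectory.topology, trajectory.coords[i])
              for i in range(trajectory.n_frames)]
    pdb = bpdb.PDBFile()
    pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


def coarse_grain(structure: AtomicStructure) -> CoarseStructure:
    """One node per residue at the C-alpha position.

    Residues without a CA atom (waters, ligands, ions) are dropped with a
    log line.
    """
    mask = structure.atom_names == "CA"
    n_dropped = len(set(zip(structure.chain_ids, structure.res_ids))) - int(
        mask.sum()
    )
    if n_dropped > 0:
        logger.info("coarse_grain: dropped %d residue(s) without a CA atom",
                    n_dropped)
    return CoarseStructure(
        residue_ids=structure.res_ids[mask],
        chain_ids=structure.chain_ids[mask],
        coords=structure.coords[mask],
        source_tag="coarse-grained CA",
    )


def load_node_table(path) -> CoarseStructure:
    """Whitespace-delimited node table: residue_index chain x y z."""
    table = pd.read_csv(
        path, sep=r"\s+", comment="#",
        names=["residue_index", "chain", "x", "y", "z"],
    )
    return CoarseStructure(
        residue_ids=table["residue_index"].to_numpy(),
        chain_ids=table["chain"].astype(str).to_numpy(dtype=object),
        coords=table[["x", "y", "z"]].to_numpy(),
        source_tag=str(path),
    )


def save_node_table(structure: CoarseStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_index chain x y z\n")
        for rid, chain, xyz in zip(structure.residue_ids,
                                   structure.chain_ids, structure.coords):
            fh.write(f"{rid} {chain} {xyz[0]:.4f} {xyz[1]:.4f} "
                     f"{xyz[2]:.4f}\n")


def load_trace(csv_path, sidecar_path=None) -> RampTrace:
    """Delimited trace (time_ms, voltage_mV, current_pA) + JSON sidecar.

    The sidecar provides capacitance_pF (required), junction_mV, rmp_mV and
    label.  Defaults to ``<csv_path>.json``.
    """
    table = pd.read_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return RampTrace(
        voltage_mv=table["voltage_mV"].to_numpy(),
        current_pa=table["current_pA"].to_numpy(),
        capacitance_pf=float(meta["capacitance_pF"]),
        time_ms=(table["time_ms"].to_numpy()
                 if "time_ms" in table.columns else None),
        junction_offset_mv=float(meta.get("junction_mV", 0.0)),
        rmp_mv=meta.get("rmp_mV"),
        label=meta.get("label", Path(str(csv_path)).stem),
    )


def save_trace(trace: RampTrace, csv_path, sidecar_path=None) -> None:
    columns = {"voltage_mV": trace.voltage_mv,
               "current_pA": trace.current_pa}
    if trace.time_ms is not None:
        columns = {"time_ms": trace.time_ms, **columns}
    pd.DataFrame(columns).to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    meta = {
        "capacitance_pF": trace.capacitance_pf,
        "junction_mV": trace.junction_offset_mv,
        "rmp_mV": trace.rmp_mv,
        "label": trace.label,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t")
    for column in ("rhinosinusitis", "male_infertility", "r117h_t5_cis",
                   "ivs8_t5_cis_pathogenic"):
        if column in cohort.columns:
            cohort[column] = cohort[column].astype("boolean")
    return cohort


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def load_panel(path) -> VariantPanel:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return VariantPanel.from_dict(spec)


def save_panel(panel: VariantPanel, path) -> None:
    spec = {"variants": {}}
    for name, variant in panel.variants.items():
        entry: dict = {"class": variant.vclass}
        if variant.phase_column is not None:
            entry["phase_column"] = variant.phase_column
            entry["class_if_cis"] = variant.class_if_cis
        spec["variants"][name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
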