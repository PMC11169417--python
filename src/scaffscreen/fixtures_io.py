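"""File I/O and seeded synthetic-data generation.

Every scenario the toolkit analyzes can be generated here with known ground
truth, so the whole pipeline — enumeration, scaffold indexing, hierarchical
screening, and the bioassay fits — is testable without any downloads:

* ``generate_planted_library``: an amide-coupling combinatorial library over
  ring-system "cores" x acyclic amines, with a known scaffold partition and
  planted pharmacophore actives (aromatic-nitrogen cores).
* ``generate_ephys``: Boltzmann-gated voltage-clamp sweeps per simulated
  cell with known V1/2, k, reversal and capacitance.
* ``generate_imaging``: calcium traces with baseline/agonist/KCl epochs.
* ``generate_dose_response``: inhibition tables from a known IC50/Hill.
* ``generate_behavior``: paw-withdrawal time courses with a known effect.

All randomness flows through one ``numpy.random.Generator`` passed
explicitly; identical seeds give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .bioassay import BehaviorSeries, ImagingTrace, SweepProtocol, SweepSet
from .enumeration import BuildingBlock, LibraryRecord, ReactionTemplate, canonical_smiles

logger = logging.getLogger("scaffscreen.fixtures_io")

__all__ = [
    "FixtureSpec",
    "generate_planted_library",
    "generate_ephys",
    "generate_imaging",
    "generate_dose_response",
    "generate_behavior",
    "read_smiles_file",
    "write_smiles_file",
    "write_library",
    "read_csv_checked",
    "read_sdf_conformers",
]

AMIDE_COUPLING = (
    "[CX3:1](=[OX1:2])[OX2H1].[NX3;H2;!$(NC=O):3]>>[C:1](=[O:2])[N:3]"
)

# ring-system carboxylic-acid cores; `active` marks the planted aromatic-N
# pharmacophore that the synthetic scorer rewards
CORES = [
    ("core_benzoic", "OC(=O)c1ccccc1", False),
    ("core_naphthoic", "OC(=O)c1ccc2ccccc2c1", False),
    ("core_thiophene", "OC(=O)c1cccs1", False),
    ("core_benzofuran", "OC(=O)c1cc2ccccc2o1", False),
    ("core_biphenyl", "OC(=O)c1ccc(-c2ccccc2)cc1", False),
    ("core_benzothiophene", "OC(=O)c1cc2ccccc2s1", False),
    ("core_nicotinic", "OC(=O)c1cccnc1", True),
    ("core_quinoline", "OC(=O)c1ccc2ccccc2n1", True),
    ("core_pyrimidine", "OC(=O)c1cncnc1", True),
]


@dataclass
class FixtureSpec:
    """Seed + scenario parameters for one synthetic dataset."""

    seed: int
    scenario: str
    parameters: dict = field(default_factory=dict)

    def p(self, key, default=None):
        return self.parameters.get(key, default)


def _acyclic_amines(n: int) -> list[tuple[str, str]]:
    """n distinct acyclic primary amines, generated systematically."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    length = 1
    while len(out) < n:
        candidates = [f"N{'C' * length}"]
        # methyl branches and ether oxygens along the chain
        for j in range(1, length):
            candidates.append("N" + "C" * j + "(C)" + "C" * (length - j))
        for j in range(2, length):
            candidates.append("N" + "C" * j + "O" + "C" * (length - j - 1))
        for variant in candidates:
            mol = Chem.MolFromSmiles(variant)
            if mol is None:
                continue
            can = canonical_smiles(mol)
            if can in seen:
                continue
            seen.add(can)
            out.append((f"amine_{len(out):03d}", variant))
            if len(out) == n:
                break
        length += 1
        if length > 80:  # safety: enough chemistry for any test size
            raise ValueError(f"cannot generate {n} distinct amines")
    return out


def generate_planted_library(spec: FixtureSpec):
    """Building blocks + template + ground truth for a planted-active library.

    Parameters: ``n_scaffolds`` (2..9, default 9), ``n_per_scaffold``
    (default 12).  Actives are the aromatic-nitrogen cores among the first
    n_scaffolds; truth lists their ids and the planted motif SMARTS.
    """
    n_scaffolds = int(spec.p("n_scaffolds", 9))
    n_per = int(spec.p("n_per_scaffold", 12))
    if not 2 <= n_scaffolds <= len(CORES):
        raise ValueError(f"n_scaffolds must be in [2, {len(CORES)}]")
    if n_per < 1:
        raise ValueError("n_per_scaffold must be >= 1")
    planted_fraction = spec.p("planted_fraction")
    cores = list(CORES[:n_scaffolds])
    if planted_fraction == 0:
        cores = [(cid, smi, False) for cid, smi, _ in cores]
    acids = [
        BuildingBlock.from_smiles(smi, cid, roles=("acid",)) for cid, smi, _a in cores
    ]
    amines = [
        BuildingBlock.from_smiles(smi, aid, roles=("amine",))
        for aid, smi in _acyclic_amines(n_per)
    ]
    template = ReactionTemplate(
        template_id="amide_coupling",
        transform=AMIDE_COUPLING,
        roles=["acid", "amine"],
    )
    truth = {
        "seed": spec.seed,
        "n_scaffolds": n_scaffolds,
        "n_per_scaffold": n_per,
        "active_core_ids": [cid for cid, _s, active in cores if active],
        "core_ids": [cid for cid, _s, _a in cores],
        "planted_motif": "[n]",
        "expected_library_size": n_scaffolds * n_per,
    }
    return {"acid": acids, "amine": amines}, template, truth


def generate_ephys(spec: FixtureSpec, rng: np.random.Generator):
    """Simulated voltage-clamp cells with Boltzmann-gated Na+ currents.

    Current model per step V:
      I(V) = gmax * m(V) * (V - Vrev) * h(t),  m(V) = 1/(1+exp((V1/2-V)/k)),
    with a fast rising / inactivating envelope in time and Gaussian noise of
    sd ``noise_sd`` (fraction of peak magnitude).  Ground truth carries every
    generating parameter per cell.
    """
    n_cells = int(spec.p("n_cells", 10))
    noise_sd = float(spec.p("noise_sd", 0.0))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    v_half = float(spec.p("V_half", -20.0))
    k = float(spec.p("k", 6.0))
    v_rev = float(spec.p("V_rev", 60.0))
    gmax = float(spec.p("gmax_ns", 20.0))          # nS -> pA/mV
    duration = float(spec.p("step_duration_ms", 200.0))
    protocol = SweepProtocol(
        holding_mv=float(spec.p("holding_mv", -60.0)),
        step_start_mv=float(spec.p("step_start_mv", -70.0)),
        step_stop_mv=float(spec.p("step_stop_mv", 60.0)),
        step_increment_mv=float(spec.p("step_increment_mv", 5.0)),
        step_duration_ms=duration,
    )
    t = np.arange(0.0, duration + 0.05, 0.05)
    cells, truth_cells = [], []
    for i in range(n_cells):
        cap = float(rng.normal(15.0, 2.0))
        cap = max(cap, 5.0)
        vh_i = v_half + float(rng.normal(0.0, spec.p("cell_sd_mv", 0.0)))
        sweeps = {}
        for v in protocol.steps:
            v = float(v)
            m = 1.0 / (1.0 + np.exp((vh_i - v) / k))
            peak = gmax * m * (v - v_rev)  # pA (negative below Vrev)
            envelope = (1.0 - np.exp(-np.clip(t - 1.0, 0, None) / 0.5)) ** 3 * np.exp(
                -np.clip(t - 1.0, 0, None) / 15.0
            )
            envelope[t < 1.0] = 0.0
            trace = peak * envelope
            if noise_sd > 0:
                trace = trace + rng.normal(0.0, noise_sd * max(abs(peak), 1.0), t.size)
            sweeps[v] = trace
        cells.append(
            SweepSet(protocol=protocol, time_ms=t, sweeps=sweeps,
                     capacitance_pf=cap, cell_id=f"cell_{i:03d}")
        )
        truth_cells.append({"cell_id": f"cell_{i:03d}", "V_half": vh_i, "k": k,
                            "V_rev": v_rev, "gmax_ns": gmax, "capacitance_pf": cap})
    truth = {"seed": spec.seed, "noise_sd": noise_sd, "cells": truth_cells}
    return cells, truth


def generate_imaging(spec: FixtureSpec, rng: np.random.Generator):
    """Calcium traces: 1-min baseline, 3-min agonist, KCl pulse; 5-s frames.

    ``responder_fraction`` of viable traces get an agonist response of
    amplitude ``amplitude`` (dF/F0); ``nonviable_fraction`` lack the KCl
    response.  Ground truth labels every trace.
    """
    n = int(spec.p("n_traces", 30))
    amplitude = float(spec.p("amplitude", 0.5))
    responder_fraction = float(spec.p("responder_fraction", 0.6))
    nonviable_fraction = float(spec.p("nonviable_fraction", 0.1))
    noise_sd = float(spec.p("noise_sd", 1.0))
    f0 = float(spec.p("F0", 100.0))
    frame = 5.0
    time = np.arange(0.0, 330.0, frame)  # 0-60 baseline, 60-240 agonist, 270-330 KCl
    baseline, agonist, kcl = (0.0, 60.0), (60.0, 240.0), (270.0, 330.0)
    traces, truth_traces = [], []
    for i in range(n):
        is_viable = rng.random() >= nonviable_fraction
        is_responder = is_viable and (rng.random() < responder_fraction)
        F = np.full(time.size, f0) + rng.normal(0.0, noise_sd, time.size)
        if is_responder:
            mask = (time >= 80) & (time < 200)
            F[mask] += amplitude * f0
        if is_viable:
            F[(time >= 280) & (time < 320)] += 0.8 * f0
        traces.append(
            ImagingTrace(time=time, F=F, baseline=baseline, agonist=agonist,
                         kcl=kcl, background=float(spec.p("background", 0.0)),
                         trace_id=f"trace_{i:03d}")
        )
        truth_traces.append({"trace_id": f"trace_{i:03d}", "responder": bool(is_responder),
                             "viable": bool(is_viable)})
    truth = {"seed": spec.seed, "amplitude": amplitude, "traces": truth_traces}
    return traces, truth


def generate_dose_response(spec: FixtureSpec, rng: np.random.Generator):
    """Fractional-inhibition table from a known Hill curve + noise."""
    ic50 = float(spec.p("IC50", 2.0))
    hill = float(spec.p("hill", 1.0))
    top = float(spec.p("top", 1.0))
    bottom = float(spec.p("bottom", 0.0))
    noise_sd = float(spec.p("noise_sd", 0.0))
    conc = np.asarray(spec.p("concentrations_um", [0.1, 0.3, 1.0, 3.0, 10.0, 30.0]), float)
    y = bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, noise_sd, conc.size), 0.0, 1.0)
    table = pd.DataFrame({"concentration_um": conc, "inhibition": y})
    truth = {"seed": spec.seed, "IC50": ic50, "hill": hill, "top": top, "bottom": bottom,
             "noise_sd": noise_sd}
    return table, truth


def generate_behavior(spec: FixtureSpec, rng: np.random.Generator):
    """PWT time courses for vehicle vs treated groups of n animals each.

    Vehicle stays at the allodynic floor; treatment adds a transient
    reversal peaking at ``t_peak_h`` with amplitude ``effect_g`` that decays
    over ``duration_h``.
    """
    n = int(spec.p("n_animals", 6))
    floor = float(spec.p("floor_g", 2.0))
    effect = float(spec.p("effect_g", 10.0))
    t_peak = float(spec.p("t_peak_h", 0.5))
    duration = float(spec.p("duration_h", 5.0))
    noise_sd = float(spec.p("noise_sd", 0.5))
    time = np.asarray(spec.p("time_h", [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0]), float)
    shape = np.where(
        time <= t_peak,
        time / t_peak,
        np.clip(1.0 - (time - t_peak) / max(duration - t_peak, 1e-9), 0.0, None),
    )
    groups = {}
    for label, amp in (("vehicle", 0.0), ("treated", effect)):
        pwt = {}
        for a in range(n):
            vals = floor + amp * shape + rng.normal(0.0, noise_sd, time.size)
            pwt[f"{label}_{a}"] = np.clip(vals, 0.0, None)
        groups[label] = BehaviorSeries(time_h=time, pwt_g=pwt, group=label)
    truth = {"seed": spec.seed, "effect_g": effect, "floor_g": floor,
             "vehicle_auc_expected": floor * (time[-1] - time[0]),
             "treated_auc_expected": floor * (time[-1] - time[0])
             + effect * float(np.trapezoid(shape, time))}
    return groups, truth


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def read_smiles_file(path) -> list[tuple[str, str]]:
    """Line-oriented SMILES: ``<smiles>\\t<id>`` per line; '#' comments."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected '<smiles>\\t<id>'")
        if Chem.MolFromSmiles(parts[0]) is None:
            raise ValueError(f"{path}:{lineno}: unparseable SMILES {parts[0]!r}")
        out.append((parts[0], parts[1]))
    return out


def write_smiles_file(path, records: list[tuple[str, str]]) -> None:
    Path(path).write_text("".join(f"{smi}\t{rid}\n" for smi, rid in records))


def write_library(path, records: list[LibraryRecord], manifest_path=None) -> None:
    """Library as TSV with provenance columns + optional JSON manifest."""
    df = pd.DataFrame(
        [
            {"smiles": r.smiles, "record_id": r.record_id, "template_id": r.template_id,
             "block_ids": "+".join(r.block_ids), "scaffold_key": r.scaffold_key or ""}
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    if manifest_path:
        counts: dict[str, int] = {}
        for r in records:
            counts[r.template_id] = counts.get(r.template_id, 0) + 1
        Path(manifest_path).write_text(
            json.dumps({"n_records": len(records), "per_template": counts}, indent=2)
        )


def read_library(path) -> list[LibraryRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"smiles", "record_id", "template_id", "block_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        LibraryRecord(
            record_id=row.record_id, smiles=row.smiles, template_id=row.template_id,
            block_ids=tuple(row.block_ids.split("+")) if row.block_ids else (),
            scaffold_key=row.scaffold_key or None,
        )
        for row in df.itertuples()
    ]


def read_csv_checked(path, required_columns: list[str]) -> pd.DataFrame:
    """CSV read with schema validation naming any missing column."""
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_sdf_conformers(path) -> dict[str, Chem.Mol]:
    """SDF (V2000) molecules with 3D coordinates, keyed by title/_Name."""
    out = {}
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            logger.warning("%s: record %d unparseable; skipped", path, i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{i}"
        out[name] = mol
    return out


def write_sdf(path, mols: dict[str, Chem.Mol]) -> None:
    writer = Chem.SDWriter(str(path))
    for name, mol in mols.items():
        mol.SetProp("_Name", name)
        writer.write(mol)
    writer.close()
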