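"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes -- a two-domain elastic structure with a flexible linker, a
trajectory of a fluctuating pore constriction, a pair of GHK-consistent
whole-cell ramp traces, a case-control cohort with planted carrier
frequencies -- and returns the generated dataset together with a
:class:`GroundTruth` record of the planted parameters, so recovery can be
tested quantitatively.  All randomness flows from one
``numpy.random.default_rng(seed)`` per call: the same seed and
configuration always reproduce the same dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VariantPanel, classify_subject, default_panel
from .enm import CoarseStructure
from .ephys import (
    BICARBONATE_BATH,
    CONTROL_BATH,
    BathSolution,
    RampTrace,
    _rt_over_f_mv,
    ghk_reversal_shift,
)
from .pore import AtomicStructure, Trajectory

__all__ = [
    "GroundTruth",
    "gen_elastic_toy",
    "gen_pore_walls",
    "gen_pore_trajectory",
    "gen_iv_trace",
    "gen_cohort_exact",
    "gen_cohort_binomial",
]

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """The planted parameters of a generated dataset."""

    scenario: str
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {"scenario": self.scenario, "params": self.params}

        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            raise TypeError(type(obj))

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_default)


# ---------------------------------------------------------------------------
# Elastic-network dumbbell


def _sample_ball(rng, n, radius, min_spacing, anchor=None):
    """Rejection-sample n points in a ball with a minimum pairwise spacing."""
    points = [] if anchor is None else [np.asarray(anchor, dtype=float)]
    target = n + len(points)
    attempts = 0
    while len(points) < target:
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius**2:
            continue
        if points and np.min(
            np.linalg.norm(np.asarray(points) - p, axis=1)
        ) < min_spacing:
            attempts += 1
            if attempts > 20000:
                raise RuntimeError("cannot place nodes at requested density")
            continue
        points.append(p)
    return np.asarray(points)


def gen_elastic_toy(
    seed: int = 0,
    n_domain: int = 30,
    linker_len: int = 4,
    domain_radius: float = 6.0,
    linker_spacing: float = 3.5,
    min_spacing: float = 2.8,
    scenario: str = "dumbbell",
) -> tuple[CoarseStructure, GroundTruth]:
    """Two compact globular domains joined by a thin linker (or one chain).

    The dumbbell emulates a two-domain architecture whose slowest collective
    mode is the anti-correlated motion of the domains about the linker, so
    the generated linker range is the ground-truth hinge location.  Each
    domain contains a deterministic "pole" node facing the other domain,
    guaranteeing the linker is connected at a 7 A GNM cutoff.  If a sampled
    structure is nonetheless disconnected it is regenerated from a shifted
    sub-seed (logged).
    """
    if scenario == "chain":
        n = n_domain
        coords = np.zeros((n, 3))
        coords[:, 0] = linker_spacing * np.arange(n)
        structure = CoarseStructure(
            residue_ids=np.arange(1, n + 1),
            chain_ids=np.array(["A"] * n, dtype=object),
            coords=coords,
            source_tag=f"chain toy seed={seed}",
        )
        truth = GroundTruth("chain", {"n": n, "spacing": linker_spacing})
        return structure, truth
    if scenario != "dumbbell":
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_domain < 5:
        raise ValueError("domain size must be >= 5 nodes")
    if linker_len < 1:
        raise ValueError("linker length must be >= 1")

    gap = (linker_len + 1) * linker_spacing
    center_b_x = 2 * domain_radius + gap
    for attempt in range(20):
        rng = np.random.default_rng((seed, attempt))
        pole_a = np.array([domain_radius - 0.5, 0.0, 0.0])
        pole_b = np.array([-(domain_radius - 0.5), 0.0, 0.0])
        dom_a = _sample_ball(rng, n_domain - 1, domain_radius, min_spacing,
                             anchor=pole_a)
        dom_b = _sample_ball(rng, n_domain - 1, domain_radius, min_spacing,
                             anchor=pole_b)
        dom_b = dom_b + np.array([center_b_x, 0.0, 0.0])
        linker = np.zeros((linker_len, 3))
        linker[:, 0] = (domain_radius - 0.5) + linker_spacing * np.arange(
            1, linker_len + 1
        )
        # small lateral jitter keeps the linker from being exactly collinear
        linker[:, 1:] = rng.normal(0.0, 0.2, size=(linker_len, 2))
        coords = np.vstack([dom_a, linker, dom_b])
        structure = CoarseStructure(
            residue_ids=np.arange(1, coords.shape[0] + 1),
            chain_ids=np.array(["A"] * coords.shape[0], dtype=object),
            coords=coords,
            source_tag=f"dumbbell toy seed={seed}",
        )
        if _is_connected(coords, cutoff=7.0):
            break
        logger.info("dumbbell seed=%s attempt=%d disconnected; regenerating",
                    seed, attempt)
    linker_range = (n_domain, n_domain + linker_len - 1)  # 0-based, inclusive
    truth = GroundTruth(
        "dumbbell",
        {
            "seed": seed,
            "n_domain": n_domain,
            "linker_len": linker_len,
            "linker_range": linker_range,
            "domain_a_range": (0, n_domain - 1),
            "domain_b_range": (n_domain + linker_len,
                               2 * n_domain + linker_len - 1),
        },
    )
    return structure, truth


def _is_connected(coords: np.ndarray, cutoff: float) -> bool:
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import pdist, squareform

    adj = squareform(pdist(coords)) <= cutoff
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


# ---------------------------------------------------------------------------
# Pore walls and constriction trajectories


def gen_pore_walls(
    constriction_radius: float = 2.15,
    z_constriction: float = 0.0,
    z_min: float = -12.0,
    z_max: float = 12.0,
    ring_spacing: float = 1.0,
    atoms_per_ring: int = 12,
    vdw_radius: float = 1.5,
    flare: float = 0.15,
) -> AtomicStructure:
    """A walled pore along z with a planted constriction radius.

    Rings of wall atoms are stacked along z; the ring center-line radius is
    ``constriction_radius + vdw_radius`` at the constriction and widens
    quadratically (``flare`` per A^2) away from it, so the maximal inscribed
    disc at the constriction elevation has exactly the planted radius.
    """
    zs = np.arange(z_min, z_max + 0.5 * ring_spacing, ring_spacing)
    angles = np.linspace(0.0, 2 * np.pi, atoms_per_ring, endpoint=False)
    coords, res_ids = [], []
    for ring_idx, z in enumerate(zs):
        c = constriction_radius + vdw_radius + flare * (z - z_constriction) ** 2
        for ang in angles:
            coords.append([c * np.cos(ang), c * np.sin(ang), z])
            res_ids.append(ring_idx + 1)
    n = len(coords)
    return AtomicStructure(
        atom_names=np.array(["W"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        res_ids=np.array(res_ids),
        chain_ids=np.array(["W"] * n, dtype=object),
        coords=np.array(coords),
        vdw_radii=np.full(n, vdw_radius),
    )


def gen_pore_trajectory(
    mu: float,
    sigma: float,
    n_frames: int,
    scenario: str = "ou",
    seed: int = 0,
    frame_interval_ps: float = 10.0,
    relaxation_ps: float = 2.5,
    marker_vdw: float = 1.5,
    include_walls: bool = False,
    constriction_radius: float = 2.15,
) -> tuple[Trajectory, GroundTruth]:
    """Trajectory of two marker residues with a prescribed distance process.

    scenario="constant" keeps the marker separation at ``mu``;
    scenario="ou" draws a stationary mean-reverting (discrete
    Ornstein-Uhlenbeck) process with stationary mean ``mu`` and SD
    ``sigma``.  The default relaxation time (2.5 ps) is much shorter than
    the frame interval (10 ps), mimicking sparsely saved frames whose
    successive constriction distances are nearly decorrelated.  The exact
    per-frame distances are stored in the ground truth for round-trip
    tests.  Optionally a static walled pore is included for radius-profile
    analyses.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma > mu / 2:
        raise ValueError("sigma > mu/2 risks non-physical overlap; rejected")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    if scenario == "constant":
        distances = np.full(n_frames, mu)
    elif scenario == "ou":
        phi = float(np.exp(-frame_interval_ps / relaxation_ps))
        innovation_sd = sigma * np.sqrt(1.0 - phi**2)
        distances = np.empty(n_frames)
        distances[0] = mu + sigma * rng.standard_normal()
        shocks = rng.standard_normal(n_frames - 1)
        for t in range(1, n_frames):
            distances[t] = mu + phi * (distances[t - 1] - mu) \
                + innovation_sd * shocks[t - 1]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    marker_names = np.array(["M", "M"], dtype=object)
    marker_elements = np.array(["C", "C"], dtype=object)
    marker_res = np.array([1, 2])
    marker_chains = np.array(["A", "A"], dtype=object)
    marker_radii = np.full(2, marker_vdw)
    if include_walls:
        walls = gen_pore_walls(constriction_radius=constriction_radius,
                               vdw_radius=marker_vdw)
        atom_names = np.concatenate([marker_names, walls.atom_names])
        elements = np.concatenate([marker_elements, walls.elements])
        res_ids = np.concatenate([marker_res, walls.res_ids])
        chain_ids = np.concatenate([marker_chains, walls.chain_ids])
        radii = np.concatenate([marker_radii, walls.vdw_radii])
        base = np.vstack([np.zeros((2, 3)), walls.coords])
    else:
        atom_names, elements = marker_names, marker_elements
        res_ids, chain_ids, radii = marker_res, marker_chains, marker_radii
        base = np.zeros((2, 3))
    topology = AtomicStructure(atom_names, elements, res_ids, chain_ids,
                               base, radii)
    coords = np.repeat(base[None], n_frames, axis=0)
    # markers straddle the origin along y, clear of any wall constriction
    coords[:, 0, 1] = -distances / 2.0
    coords[:, 1, 1] = distances / 2.0
    times = frame_interval_ps * np.arange(n_frames, dtype=float)
    trajectory = Trajectory(topology, coords, times)
    truth = GroundTruth(
        f"pore-{scenario}",
        {
            "mu": mu,
            "sigma": sigma,
            "n_frames": n_frames,
            "seed": seed,
            "frame_interval_ps": frame_interval_ps,
            "relaxation_ps": relaxation_ps,
            "distances": distances,
            "constriction_radius": (constriction_radius if include_walls
                                    else None),
            "residue_a": ("A", 1),
            "residue_b": ("A", 2),
        },
    )
    return trajectory, truth


# ---------------------------------------------------------------------------
# GHK-consistent I-V ramp pairs


def gen_iv_trace(
    p_ratio: float,
    g_cl_ns: float = 4.0,
    g_x_ns: float | None = None,
    noise_sd_frac: float = 0.0,
    capacitance_pf: float = 25.0,
    pipette_cl_mm: float = 10.0,
    control: BathSolution = CONTROL_BATH,
    substituted: BathSolution = BICARBONATE_BATH,
    species: str = "HCO3",
    seed: int = 0,
    n_samples: int = 1250,
    ramp_mv: tuple[float, float] = (-100.0, 100.0),
    ramp_duration_ms: float = 250.0,
) -> tuple[RampTrace, RampTrace, GroundTruth]:
    """A control/substituted ramp pair consistent with a planted P_X/P_Cl.

    The control reversal potential follows from the pipette/bath chloride
    gradient; the substituted-trace reversal is shifted by the GHK forward
    map at the planted permeability ratio.  Currents are linear in voltage
    (the whole-cell I-V relation of an activated CFTR-like conductance is
    close to ohmic) with slope ``g_cl_ns`` / ``g_x_ns``; Gaussian noise with
    SD ``noise_sd_frac * max|I|`` is added per trace.
    """
    if p_ratio <= 0:
        raise ValueError("planted permeability ratio must be positive")
    if noise_sd_frac < 0:
        raise ValueError("noise SD must be non-negative")
    if g_x_ns is None:
        g_x_ns = g_cl_ns
    rng = np.random.default_rng(seed)
    rt_f = _rt_over_f_mv(control.temperature_k)
    e_rev_cl = rt_f * np.log(pipette_cl_mm / control["Cl"])
    delta = ghk_reversal_shift(p_ratio, control, substituted, species)
    e_rev_x = e_rev_cl + delta

    voltage = np.linspace(ramp_mv[0], ramp_mv[1], n_samples)
    time_ms = np.linspace(0.0, ramp_duration_ms, n_samples)

    def make(label, g_ns, e_rev):
        current = g_ns * (voltage - e_rev)
        if noise_sd_frac > 0:
            current = current + rng.normal(
                0.0, noise_sd_frac * np.max(np.abs(current)), n_samples
            )
        return RampTrace(
            voltage_mv=voltage.copy(),
            current_pa=current,
            capacitance_pf=capacitance_pf,
            time_ms=time_ms.copy(),
            label=label,
        )

    trace_cl = make("control (Cl)", g_cl_ns, e_rev_cl)
    trace_x = make(f"substituted ({species})", g_x_ns, e_rev_x)
    truth = GroundTruth(
        "iv-ramp-pair",
        {
            "p_ratio": p_ratio,
            "g_cl_ns": g_cl_ns,
            "g_x_ns": g_x_ns,
            "g_ratio": g_x_ns / g_cl_ns,
            "e_rev_cl_mv": float(e_rev_cl),
            "e_rev_x_mv": float(e_rev_x),
            "delta_e_rev_mv": float(delta),
            "noise_sd_frac": noise_sd_frac,
            "capacitance_pf": capacitance_pf,
            "seed": seed,
        },
    )
    return trace_cl, trace_x, truth


# ---------------------------------------------------------------------------
# Case-control cohorts

#: Per-variant carrier frequencies used for the binomial cohort scenario:
#: the control-arm frequencies of the screening panel's informative variants.
DEFAULT_CARRIER_FREQS = {
    "F508del": 0.031,
    "R75Q": 0.062,
    "S1235R": 0.014,
    "R117H": 0.007,
    "L967S": 0.002,
    "L997F": 0.010,
    "D1270N": 0.002,
    "D1152H": 0.0005,
    "R170H": 0.0005,
    "R74Q": 0.001,
    "IVS8T5": 0.082,
}

#: Phenotype odds multipliers by carrier stratum for the binomial scenario
#: (baseline is the control-arm phenotype rate).
DEFAULT_PHENOTYPE_MULTIPLIERS = {
    "none": 1.5,
    "one_cf": 2.5,
    "one_bd": 2.6,
    "recessive": 1.3,
}


def _empty_cohort(panel: VariantPanel, n: int) -> pd.DataFrame:
    data = {"id": [f"S{i:05d}" for i in range(n)],
            "status": ["control"] * n}
    for name in panel.variants:
        data[name] = np.zeros(n, dtype=int)
    data["spink1_n34s"] = np.zeros(n, dtype=int)
    data["r117h_t5_cis"] = pd.array([pd.NA] * n, dtype="boolean")
    data["ivs8_t5_cis_pathogenic"] = pd.array([pd.NA] * n, dtype="boolean")
    data["rhinosinusitis"] = pd.array([False] * n, dtype="boolean")
    data["male_infertility"] = pd.array([pd.NA] * n, dtype="boolean")
    return pd.DataFrame(data)


def gen_cohort_exact(
    groups: list[dict],
    panel: VariantPanel | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Deterministically plant exact subgroup counts in a cohort table.

    Each group dict has keys ``status`` ("case"/"control"), ``n``, and
    optionally ``variants`` ({name: allele count} applied to every member),
    ``spink1_n34s`` (allele count), and ``phenotypes``
    ({flag name: number of members with the flag True}).  Exact-count mode
    exists so printed contingency tables can be reproduced without sampling
    noise.
    """
    if panel is None:
        panel = default_panel()
    frames = []
    offset = 0
    for group in groups:
        n = int(group["n"])
        pheno = group.get("phenotypes", {})
        for flag, k in pheno.items():
            if k > n:
                raise ValueError(
                    f"{flag}: planted count {k} exceeds group size {n}"
                )
        df = _empty_cohort(panel, n)
        df["id"] = [f"S{offset + i:05d}" for i in range(n)]
        df["status"] = group["status"]
        for name, count in group.get("variants", {}).items():
            if name not in panel.variants:
                raise KeyError(f"variant {name!r} not in panel")
            df[name] = int(count)
        if "spink1_n34s" in group:
            df["spink1_n34s"] = int(group["spink1_n34s"])
        for flag, k in pheno.items():
            values = [True] * int(k) + [False] * (n - int(k))
            df[flag] = pd.array(values, dtype="boolean")
        frames.append(df)
        offset += n
    cohort = pd.concat(frames, ignore_index=True)
    truth = GroundTruth("cohort-exact", {"groups": groups})
    return cohort, truth


def gen_cohort_binomial(
    n_cases: int = 984,
    n_controls: int = 1224,
    carrier_freqs: dict[str, float] | None = None,
    case_odds: dict[str, float] | None = None,
    n34s_freq_controls: float = 0.02,
    n34s_freq_cases: float = 0.056,
    phenotype: str = "rhinosinusitis",
    phenotype_baseline: float = 0.102,
    phenotype_multipliers: dict[str, float] | None = None,
    panel: VariantPanel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a case-control cohort with planted carrier frequencies.

    Controls carry each variant with its ``carrier_freqs`` probability;
    cases with odds multiplied by ``case_odds`` (default 1).  Carriers are
    heterozygous (homozygosity is negligible at rare-variant frequencies).
    The phenotype flag is Bernoulli with baseline odds for controls and
    stratum-multiplied odds for cases.
    """
    if panel is None:
        panel = default_panel()
    if carrier_freqs is None:
        carrier_freqs = dict(DEFAULT_CARRIER_FREQS)
    if case_odds is None:
        case_odds = {}
    if phenotype_multipliers is None:
        phenotype_multipliers = dict(DEFAULT_PHENOTYPE_MULTIPLIERS)
    for name, freq in carrier_freqs.items():
        if not 0 <= freq <= 1:
            raise ValueError(f"carrier frequency for {name} outside [0,1]")
    if any(m <= 0 for m in case_odds.values()):
        raise ValueError("odds multipliers must be positive")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    cohort = _empty_cohort(panel, n)
    cohort.loc[: n_cases - 1, "status"] = "case"
    is_case = (cohort["status"] == "case").to_numpy()

    def _freq_for_cases(freq, odds_multiplier):
        odds = freq / (1 - freq) * odds_multiplier if freq < 1 else np.inf
        return odds / (1 + odds)

    for name, freq in carrier_freqs.items():
        p = np.where(is_case,
                     _freq_for_cases(freq, case_odds.get(name, 1.0)), freq)
        cohort[name] = (rng.random(n) < p).astype(int)
    p_n34s = np.where(is_case, n34s_freq_cases, n34s_freq_controls)
    cohort["spink1_n34s"] = (rng.random(n) < p_n34s).astype(int)

    base_odds = phenotype_baseline / (1 - phenotype_baseline)
    probs = np.full(n, phenotype_baseline)
    for i in range(n):
        if not is_case[i]:
            continue
        cls = classify_subject(cohort.iloc[i], panel)
        stratum = {"CF_carrier": "one_cf", "BD_carrier": "one_bd",
                   "CFBD_or_BDBD_recessive": "recessive",
                   "transhet_N34S": "one_bd", "none": "none"}[cls]
        odds = base_odds * phenotype_multipliers.get(stratum, 1.0)
        probs[i] = odds / (1 + odds)
    cohort[phenotype] = pd.array(rng.random(n) < probs, dtype="boolean")
    truth = GroundTruth(
        "cohort-binomial",
        {
            "n_cases": n_cases,
            "n_controls": n_controls,
            "carrier_freqs": carrier_freqs,
            "case_odds": case_odds,
            "n34s_freq_controls": n34s_freq_controls,
            "n34s_freq_cases": n34s_freq_cases,
            "phenotype": phenotype,
            "phenotype_baseline": phenotype_baseline,
            "phenotype_multipliers": phenotype_multipliers,
            "seed": seed,
        },
    )
    return cohort, truth
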