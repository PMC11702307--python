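"""Seeded generators for every input the pipeline consumes.

Real inputs to these analyses — AFM force traces, participant-level
questionnaire tables, Sanger-called coding sequences — are either
instrument-bound or not publicly shareable.  This module synthesizes all of
them with known ground truth so every downstream operation can be tested by
recovery:

* rupture forces drawn from the Evans–Ritchie density by inverse-CDF
  sampling, and whole dynamic-force-spectroscopy experiments;
* Poisson tip–cell contact events at a target adhesion frequency;
* force–displacement pulling traces with thermal cantilever noise;
* thermal-deflection traces for equipartition stiffness calibration;
* a 624-participant cohort with ~2.2% heterozygous carriers whose group
  score distributions are calibrated to the study's published summary
  statistics;
* mutated copies of a reference coding sequence (substitutions including
  heterozygous IUPAC calls, insertions, deletions);
* toy receptor–ligand atomic coordinate sets with planted clash geometry.

Every generator is a pure function of its configuration and an integer
seed, and emits a machine-readable truth record for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bell_evans as be
from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .trace_analysis import ForceTrace

__all__ = [
    "DfsExperimentConfig",
    "CohortGroupCalibration",
    "CohortConfig",
    "DEFAULT_COHORT_CONFIG",
    "sample_rupture_forces",
    "simulate_contact_events",
    "synthesize_force_trace",
    "simulate_thermal_trace",
    "simulate_dfs_experiment",
    "generate_synthetic_cohort",
    "generate_mutant_sequences",
    "generate_toy_complex",
]


# --------------------------------------------------------------------------
# force spectroscopy
# --------------------------------------------------------------------------

def sample_rupture_forces(
    params: be.BellEvansParams,
    loading_rate: float,
    n: int,
    seed,
) -> np.ndarray:
    """Draw ``n`` rupture forces from the Evans–Ritchie density (pN).

    Inverse-CDF sampling through :func:`lynxkit.bell_evans.inverse_cdf`;
    reproducible for a fixed seed.  ``seed`` may be an int or a numpy
    Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    # keep u strictly inside (0, 1) for the open-interval quantile function
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return np.asarray(be.inverse_cdf(params, loading_rate, u))


def simulate_contact_events(mean_bonds: float, trials: int, seed) -> dict:
    """Poisson bond formation over repeated tip–cell contacts.

    Returns the per-trial bond counts plus the realized adhesion frequency
    (fraction of trials with >= 1 bond) and the single-bond fraction among
    adhesive trials.  Keeping the adhesion frequency near 30% keeps the
    single-bond fraction above ~83%.
    """
    if mean_bonds < 0:
        raise ValueError("mean bond number must be >= 0")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean_bonds, size=trials)
    adhesive = counts >= 1
    n_adh = int(adhesive.sum())
    return {
        "bond_counts": counts,
        "adhesion_frequency": n_adh / trials,
        "single_bond_fraction": (int((counts == 1).sum()) / n_adh) if n_adh else float("nan"),
    }


def synthesize_force_trace(
    ks: float,
    retraction_speed: float,
    rupture_force: float,
    noise_sd: float,
    sample_rate: float = 10_000.0,
    seed=0,
    trace_id: str = "trace",
    approach_samples: int = 50,
    dwell_samples: int = 20,
) -> tuple[ForceTrace, dict]:
    """Build one pulling trace with a planted rupture.

    The retract phase ramps force linearly at slope ``ks`` (pN/nm) in
    force-vs-displacement until ``rupture_force`` — the final pre-rupture
    sample sits exactly at the planted force — then drops to a zero
    baseline.  Gaussian noise of SD ``noise_sd`` is added everywhere.
    Returns the trace and a truth record of the planted (Fu, ks).
    """
    for name, v in [("ks", ks), ("retraction_speed", retraction_speed),
                    ("rupture_force", rupture_force), ("sample_rate", sample_rate)]:
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and rupture_force <= 5.0 * noise_sd:
        raise ValueError(
            f"rupture force {rupture_force} pN is at or below the detection "
            f"floor for noise SD {noise_sd} pN"
        )
    rng = np.random.default_rng(seed)

    step = retraction_speed / sample_rate  # nm per retract sample
    n_ramp = int(math.ceil(rupture_force / (ks * step)))
    ramp_disp = np.arange(1, n_ramp + 1) * step
    ramp_force = ks * ramp_disp
    ramp_disp[-1] = rupture_force / ks  # land exactly on the planted rupture
    ramp_force[-1] = rupture_force
    n_tail = max(4, n_ramp // 2)  # post-rupture baseline segment
    tail_disp = ramp_disp[-1] + np.arange(1, n_tail + 1) * step

    disp = np.concatenate([
        np.zeros(approach_samples + dwell_samples),
        ramp_disp,
        tail_disp,
    ])
    force = np.concatenate([
        np.zeros(approach_samples + dwell_samples),
        ramp_force,
        np.zeros(n_tail),
    ])
    phase = np.concatenate([
        np.repeat("approach", approach_samples),
        np.repeat("dwell", dwell_samples),
        np.repeat("retract", n_ramp + n_tail),
    ]).astype(object)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=force.size)

    trace = ForceTrace(
        displacement=disp,
        force=force,
        phase=phase,
        retraction_speed=retraction_speed,
        sample_rate=sample_rate,
        trace_id=trace_id,
    )
    truth = {
        "trace_id": trace_id,
        "unbinding_force": float(rupture_force),
        "system_spring_constant": float(ks),
        "loading_rate": float(ks * retraction_speed),
        "noise_sd": float(noise_sd),
    }
    return trace, truth


def simulate_thermal_trace(
    stiffness: float,
    temperature: float = DEFAULT_TEMPERATURE,
    n: int = 100_000,
    seed=0,
) -> np.ndarray:
    """Thermal cantilever deflection: i.i.d. Gaussian, variance kBT/k (nm²)."""
    if not stiffness > 0:
        raise ValueError("stiffness must be positive")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(thermal_energy(temperature) / stiffness)
    return rng.normal(0.0, sd, size=n)


@dataclass(frozen=True)
class DfsExperimentConfig:
    """One simulated dynamic-force-spectroscopy experiment.

    Defaults mirror the study conditions: five loading-rate groups spanning
    the ~30–4,000 pN/s window, 300 rupture events per group, γ = 0.5 nm at
    25 °C, and a 9.7 pN/nm system spring constant.
    """

    params: be.BellEvansParams
    loading_rates: tuple = (30.0, 100.0, 300.0, 1000.0, 3000.0)  # pN/s
    events_per_rate: int = 300
    system_spring_constant: float = 9.7  # pN/nm

    def __post_init__(self) -> None:
        if len(self.loading_rates) < 2:
            raise ValueError("need at least 2 loading rates")
        if self.events_per_rate < 1:
            raise ValueError("events_per_rate must be >= 1")


def simulate_dfs_experiment(config: DfsExperimentConfig, seed) -> tuple[pd.DataFrame, dict]:
    """Simulate a full DFS experiment: a flat event table plus ground truth.

    For each configured loading rate, rupture forces are drawn from the
    Evans–Ritchie density; the implied retraction speed is rf/ks.  The
    event table has columns trace_id, loading_rate_pN_per_s, Fu_pN,
    ks_pN_per_nm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rf in config.loading_rates:
        forces = sample_rupture_forces(config.params, rf, config.events_per_rate, rng)
        for i, fu in enumerate(forces):
            rows.append((f"rf{rf:g}_{i}", rf, float(fu), config.system_spring_constant))
    events = pd.DataFrame(rows, columns=["trace_id", "loading_rate_pN_per_s", "Fu_pN", "ks_pN_per_nm"])
    truth = {
        "k0_per_s": config.params.k0,
        "gamma_nm": config.params.gamma,
        "temperature_K": config.params.temperature,
        "lifetime_s": config.params.lifetime,
        "loading_rates_pN_per_s": list(config.loading_rates),
        "events_per_rate": config.events_per_rate,
    }
    return events, truth


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGroupCalibration:
    """Target score distribution for one genotype group on one instrument."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort layout.

    ``instrument_calibration`` maps instrument id →
    {"reference": CohortGroupCalibration, "carrier": CohortGroupCalibration}.
    Group SDs correspond to SEM·√n of the published group summaries.
    """

    n_participants: int = 624
    carrier_frequency: float = 14 / 624  # ~2.2% heterozygous carriers
    carrier_label: str = "Q39H"
    instrument_calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_frequency <= 1:
            raise ValueError("carrier_frequency must lie in [0, 1]")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


def _default_calibration() -> dict:
    # Total-score calibration from the study's replication cohort:
    # STICSA 71.09 ± 1.04 SEM (n=469) vs 91.778 ± 6.184 SEM (n=15);
    # STAI 82.76 ± 1.30 (n=469) vs 99.0 ± 6.53 (n=15); SD = SEM·√n.
    return {
        "STICSA": {
            "reference": CohortGroupCalibration(71.09, 1.04 * math.sqrt(469)),
            "carrier": CohortGroupCalibration(91.778, 6.184 * math.sqrt(15)),
        },
        "STAI": {
            "reference": CohortGroupCalibration(82.76, 1.30 * math.sqrt(469)),
            "carrier": CohortGroupCalibration(99.0, 6.53 * math.sqrt(15)),
        },
        "CBI": {
            "reference": CohortGroupCalibration(43.46, 1.62 * math.sqrt(206)),
            "carrier": CohortGroupCalibration(30.35, 4.79 * math.sqrt(9)),
        },
    }


#: Calibration profile matching the study cohort's published group
#: summaries (624 participants, ~2.2% carriers).  These are calibration
#: targets for the generator, not data.
DEFAULT_COHORT_CONFIG = CohortConfig(instrument_calibration=_default_calibration())


def _compose_item_responses(target_sum: int, n_items: int, lo: int, hi: int, rng) -> np.ndarray:
    """Random integer composition of ``target_sum`` into item weights in [lo, hi]."""
    if not n_items * lo <= target_sum <= n_items * hi:
        raise ValueError(
            f"target sum {target_sum} infeasible for {n_items} items in [{lo}, {hi}]"
        )
    weights = np.full(n_items, lo, dtype=int)
    remaining = target_sum - n_items * lo
    while remaining > 0:
        open_items = np.flatnonzero(weights < hi)
        # spread the remainder over a random subset of non-saturated items
        take = min(remaining, open_items.size)
        chosen = rng.choice(open_items, size=take, replace=False)
        weights[chosen] += 1
        remaining -= take
    return weights


def generate_synthetic_cohort(
    config: CohortConfig = DEFAULT_COHORT_CONFIG,
    seed=0,
    questionnaire_specs=None,
) -> tuple[pd.DataFrame, dict]:
    """Generate an item-level cohort table with planted group score targets.

    Carriers are drawn Binomial(n, carrier_frequency).  For each
    participant and instrument, a target total score is drawn from the
    group's calibration normal, truncated (by re-draw, then clamped) to the
    instrument's achievable range, and item responses are produced by a
    random integer composition of that target respecting per-item bounds
    and reverse-key bookkeeping — so scoring the items recovers the planted
    target exactly.

    Returns a long-format table (participant_id, genotype_class,
    instrument, item_id, response) and a truth record with per-participant
    targets and group summaries.
    """
    from .cohort_stats import default_specs  # local import: avoid cycle

    specs = questionnaire_specs or default_specs()
    missing = set(config.instrument_calibration) - set(s.instrument for s in specs.values())
    if missing:
        raise ValueError(f"no questionnaire spec for calibrated instruments: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    carrier_mask = rng.random(config.n_participants) < config.carrier_frequency
    rows = []
    targets: dict = {}
    for i in range(config.n_participants):
        pid = f"P{i:04d}"
        group = config.carrier_label if carrier_mask[i] else "reference"
        group_key = "carrier" if carrier_mask[i] else "reference"
        targets[pid] = {"genotype_class": group}
        for inst, groups in config.instrument_calibration.items():
            spec = specs[inst]
            cal = groups[group_key]
            n_items = len(spec.items)
            lo_total = n_items * spec.response_min
            hi_total = n_items * spec.response_max
            target = int(round(rng.normal(cal.mean, cal.sd)))
            target = int(np.clip(target, lo_total, hi_total))
            weights = _compose_item_responses(
                target, n_items, spec.response_min, spec.response_max, rng
            )
            targets[pid][inst] = target
            for (item_id, _subscale), w in zip(spec.items, weights):
                # stored responses are raw answers; scoring re-keys reversed items
                response = (
                    spec.response_max + spec.response_min - int(w)
                    if item_id in spec.reverse_keyed
                    else int(w)
                )
                rows.append((pid, group, inst, item_id, response))
    cohort = pd.DataFrame(
        rows, columns=["participant_id", "genotype_class", "instrument", "item_id", "response"]
    )
    truth = {
        "seed": int(np.asarray(seed).item()) if np.ndim(seed) == 0 and not isinstance(seed, np.random.Generator) else None,
        "n_participants": config.n_participants,
        "n_carriers": int(carrier_mask.sum()),
        "carrier_frequency": config.carrier_frequency,
        "targets": targets,
        "calibration": {
            inst: {k: {"mean": v.mean, "sd": v.sd} for k, v in groups.items()}
            for inst, groups in config.instrument_calibration.items()
        },
    }
    return cohort, truth


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

_IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def generate_mutant_sequences(reference_cds: str, edits, seed=0) -> tuple[dict, pd.DataFrame]:
    """Apply planted edits to a reference CDS and record the truth table.

    ``edits`` is a list of dicts with keys:

    * ``kind``: "substitution" | "insertion" | "deletion"
    * ``position``: 1-based CDS position (anchor base for indels)
    * ``alt``: replacement base (substitution) or inserted sequence
    * ``length``: deleted length (deletion)
    * ``heterozygous``: substitutions only — encode as an IUPAC ambiguity
      code covering {ref, alt} (Sanger-style single-read representation)

    Returns ``{sample_id: sequence}`` (one mutant record; the reference is
    not included) and a truth DataFrame of the planted edits.  Overlapping
    edits are rejected.
    """
    ref = reference_cds.upper()
    seq = list(ref)
    edits = sorted(edits, key=lambda e: e["position"])
    occupied: set = set()
    rows = []
    # apply right-to-left so earlier coordinates stay valid
    for e in reversed(edits):
        pos = e["position"]
        if not 1 <= pos <= len(ref):
            raise ValueError(f"edit position {pos} outside CDS of length {len(ref)}")
        kind = e["kind"]
        span = range(pos, pos + (e.get("length", 1) if kind == "deletion" else 1))
        if occupied & set(span):
            raise ValueError(f"overlapping edits at position {pos}")
        occupied |= set(span)
        if kind == "substitution":
            ref_base = ref[pos - 1]
            alt = e["alt"].upper()
            if alt == ref_base:
                raise ValueError(f"substitution at {pos} does not change the base")
            if e.get("heterozygous"):
                written = _IUPAC_HET[frozenset({ref_base, alt})]
            else:
                written = alt
            seq[pos - 1] = written
            rows.append((kind, pos, ref_base, alt, bool(e.get("heterozygous"))))
        elif kind == "insertion":
            ins = e["alt"].upper()
            seq.insert(pos, ins)  # insert after the anchor base
            rows.append((kind, pos, "", ins, False))
        elif kind == "deletion":
            length = int(e.get("length", 1))
            deleted = ref[pos - 1 : pos - 1 + length]
            del seq[pos - 1 : pos - 1 + length]
            rows.append((kind, pos, deleted, "", False))
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    truth = pd.DataFrame(
        rows[::-1], columns=["kind", "cds_position", "ref", "alt", "heterozygous"]
    )
    return {"sample": "".join(seq)}, truth


# --------------------------------------------------------------------------
# toy complexes
# --------------------------------------------------------------------------

def generate_toy_complex(
    n_receptor_atoms: int = 40,
    n_ligand_atoms: int = 30,
    clashes_per_offset=(6, 3, 0),
    clash_cutoff: float = 3.0,
    step: float = 1.0,
    seed=0,
):
    """Build a toy receptor/ligand pair with planted clash geometry.

    ``clashes_per_offset[j]`` is the number of inter-body heavy-atom pairs
    closer than ``clash_cutoff`` once the ligand has been moved outward by
    ``j × step`` Å along +x (the receptor→ligand surface vector).  The
    sequence must be non-increasing and reach its minimum at the planted
    optimal offset.  Returns (receptor Structure, ligand Structure,
    truth dict); the two surface selections are the receptor atoms at
    x ≈ 0 and the ligand clash atoms, recorded in the truth dict.
    """
    from .structure_tools import Atom, Structure  # local import: avoid cycle

    counts = list(clashes_per_offset)
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("clash counts must be non-increasing with offset")
    n_clash = counts[0]
    if n_clash > min(n_receptor_atoms, n_ligand_atoms):
        raise ValueError("more planted clashes than atoms")

    rng = np.random.default_rng(seed)
    # receptor: clash partners on the x=0 plane, fillers well behind it
    rec_atoms = []
    for i in range(n_receptor_atoms):
        if i < n_clash:
            y, z = 10.0 * i, 0.0
            x = 0.0
        else:
            x = -rng.uniform(8.0, 20.0)
            y, z = rng.uniform(-30.0, 30.0, size=2)
        rec_atoms.append(Atom("R", i + 1, "GLY", "CA", "C", float(x), float(y), float(z)))

    # ligand: clash atom j sits opposite receptor atom j at a distance chosen
    # so the pair stops clashing exactly at its planted resolution offset
    resolve_offset = []
    for j in range(n_clash):
        # pair j resolves at the smallest offset index o with counts[o] <= j;
        # None when it still clashes at the largest scanned offset
        o = next((k for k, c in enumerate(counts) if c <= j), None)
        resolve_offset.append(o)
    lig_atoms = []
    for i in range(n_ligand_atoms):
        if i < n_clash:
            o = resolve_offset[i]
            if o is None:
                d = clash_cutoff - (len(counts) - 1) * step - 0.5 * step
            else:
                # distance in [cutoff − o·step, cutoff − (o−1)·step): clash
                # persists through offset o−1 and resolves at offset o
                d = clash_cutoff - o * step + 0.5 * step
            if d <= 0:
                raise ValueError("clash geometry infeasible: required distance <= 0")
            x, y, z = d, 10.0 * i, 0.0
        else:
            x = rng.uniform(clash_cutoff + len(counts) * step + 5.0, 40.0)
            y, z = rng.uniform(-30.0, 30.0, size=2)
        lig_atoms.append(Atom("L", i + 1, "GLY", "CA", "C", float(x), float(y), float(z)))

    receptor = Structure(rec_atoms, metadata={"body": "receptor"})
    ligand = Structure(lig_atoms, metadata={"body": "ligand"})
    truth = {
        "clash_cutoff": clash_cutoff,
        "step": step,
        "offsets": [j * step for j in range(len(counts))],
        "planted_clashes_per_offset": counts,
        "optimal_offset": counts.index(min(counts)) * step,
        "receptor_surface_indices": list(range(n_clash)) or [0],
        "ligand_surface_indices": list(range(n_clash)) or [0],
    }
    return receptor, ligand, truth
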