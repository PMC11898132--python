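"""Synthetic pedigree and litter-size records with the model's exact
statistical structure.

The generator emulates a closed nucleus flock managed in rotating ram
families: each generation one sire (plus replacement) serves per family
and dams are systematically moved to the next family before mating, which
limits inbreeding. Breeding values follow the pedigree (founders
MVN(0, G), offspring mid-parent plus Mendelian sampling shrunk by parental
inbreeding), permanent-environment coefficients are MVN(0, P) per ewe,
and each surviving parity contributes a liability

    year + month + phi(t)'beta + phi(t)'a + phi(t)'p + e,

thresholded into 2 or 3 ordered categories. Sequential retention draws
reproduce the declining record counts at later parities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .design import RESIDUAL_CLASSES
from .pedigree import Pedigree

__all__ = [
    "SimulationScenario",
    "SyntheticDataset",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_records",
    "line_scenario",
    "simulate_dataset",
]

_MONTH_NAMES = ("9", "10", "11")
_MONTH_PROBS = (0.5, 0.3, 0.2)


@dataclass
class SimulationScenario:
    """Everything that defines one simulated flock and trait."""

    line: str = "prolific"
    n_founders: int = 165            # founder females
    n_generations: int = 5           # generations bred after the founders
    ewes_per_generation: int = 165
    n_families: int = 7
    rams_per_family: int = 2         # a sire and its replacement
    generation_interval: int = 4     # years between generations
    true_G: np.ndarray = field(default_factory=lambda: 0.1 * np.eye(3))
    true_P: np.ndarray = field(default_factory=lambda: 0.2 * np.eye(3))
    true_resid: tuple = (1.0, 1.0, 1.0)   # per residual class
    thresholds: tuple = (0.0, 1.0)
    year_sd: float = 0.2
    month_effects: tuple = (0.0, -0.1, -0.2)
    beta: np.ndarray = field(default_factory=lambda: np.zeros(3))
    parity_retention: tuple = (0.7, 0.6, 0.7, 0.75, 0.8)
    n_categories: int = 3
    rotate_families: bool = True
    seed: int = 2024

    @property
    def order(self) -> int:
        return np.asarray(self.true_G).shape[0] - 1

    def class_of(self, parity: int) -> int:
        return RESIDUAL_CLASSES[self.line][int(parity)]


def line_scenario(line: str, n_ewes: int | None = None,
                  seed: int = 2024) -> SimulationScenario:
    """Ready-made scenario shaped like one of the two selection lines.

    prolific: 3 liability categories, residual classes {1},{2-4},{5,6},
    ~990 ewes over six cohorts, 29-ish year levels, mean ~2.8 lambings.
    conventional: 2 categories, classes {1},{2,6},{3-5}, ~860 ewes,
    19-ish year levels, mean ~3.0 lambings. ``n_ewes`` rescales the
    cohort size while keeping every rate and parameter fixed.
    """
    if line == "prolific":
        per_gen = 165
        scen = SimulationScenario(
            line="prolific",
            n_founders=per_gen,
            ewes_per_generation=per_gen,
            n_generations=5,
            generation_interval=4,
            true_G=np.array(
                [[0.10, 0.02, 0.01],
                 [0.02, 0.04, 0.00],
                 [0.01, 0.00, 0.02]]
            ),
            true_P=np.array(
                [[0.20, 0.00, 0.05],
                 [0.00, 0.05, 0.00],
                 [0.05, 0.00, 0.08]]
            ),
            true_resid=(0.77, 0.74, 0.79),
            thresholds=(0.0, 1.0),
            beta=np.array([-0.07, 0.15, 0.0]),
            parity_retention=(0.70, 0.60, 0.70, 0.75, 0.80),
            n_categories=3,
            seed=seed,
        )
    elif line == "conventional":
        per_gen = 143
        scen = SimulationScenario(
            line="conventional",
            n_founders=per_gen,
            ewes_per_generation=per_gen,
            n_generations=5,
            generation_interval=3,
            true_G=np.array(
                [[0.30, 0.05, 0.02],
                 [0.05, 0.10, 0.00],
                 [0.02, 0.00, 0.05]]
            ),
            true_P=np.array(
                [[0.45, 0.05, 0.02],
                 [0.05, 0.12, 0.00],
                 [0.02, 0.00, 0.06]]
            ),
            true_resid=(1.0, 1.0, 1.0),
            thresholds=(0.0,),
            beta=np.array([-2.6, -0.15, 0.05]),
            parity_retention=(0.66, 0.79, 0.70, 0.65, 0.85),
            n_categories=2,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown line {line!r}")
    if n_ewes is not None:
        per_gen = max(scen.n_families, round(n_ewes / (scen.n_generations + 1)))
        scen = replace(
            scen, n_founders=per_gen, ewes_per_generation=per_gen
        )
    return scen


def simulate_pedigree(scenario: SimulationScenario,
                      rng: np.random.Generator | None = None) -> tuple:
    """Discrete-generation pedigree under rotating-family matings.

    Returns (Pedigree, sex-coded metadata DataFrame). Families rotate the
    dams one family forward each generation (when ``rotate_families``), so
    a dam is never mated to a sire of her own birth family.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    nf = scenario.n_families
    if scenario.ewes_per_generation < nf or scenario.n_founders < nf:
        raise ValueError(
            "need at least one ewe per family per generation "
            f"({scenario.ewes_per_generation} ewes for {nf} families)"
        )
    rows = []  # animal, sire, dam, sex, birth_year, family, generation
    counter = [0]

    def new_id(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]:05d}"

    males = {0: []}
    females = {0: []}
    for f in range(nf):
        for _ in range(scenario.rams_per_family):
            aid = new_id("M")
            rows.append((aid, "0", "0", "M", 0, f, 0))
            males[0].append((aid, f))
    for i in range(scenario.n_founders):
        aid = new_id("F")
        f = i % nf
        rows.append((aid, "0", "0", "F", 0, f, 0))
        females[0].append((aid, f))

    for g in range(1, scenario.n_generations + 1):
        year = g * scenario.generation_interval
        # one active sire per family from last generation's males
        sire_of = {}
        for aid, f in males[g - 1]:
            sire_of.setdefault(f, aid)
        # rotate each dam to the next family and mate within it
        matings = []
        for aid, f in females[g - 1]:
            fam = (f + 1) % nf if scenario.rotate_families else f
            if fam not in sire_of:
                raise ValueError(f"no sire available in family {fam}")
            matings.append((sire_of[fam], aid, fam))
        if not matings:
            raise ValueError("no matings possible: no dams")
        males[g] = []
        females[g] = []
        # every family must produce its sire and replacement
        by_family = {f: [] for f in range(nf)}
        for mt in matings:
            by_family[mt[2]].append(mt)
        for f in range(nf):
            if not by_family[f]:
                raise ValueError(f"no matings in family {f}")
            for r in range(scenario.rams_per_family):
                sire, dam, fam = by_family[f][r % len(by_family[f])]
                aid = new_id("M")
                rows.append((aid, sire, dam, "M", year, fam, g))
                males[g].append((aid, fam))
        order = rng.permutation(len(matings))
        for k in range(scenario.ewes_per_generation):
            sire, dam, fam = matings[order[k % len(matings)]]
            aid = new_id("F")
            rows.append((aid, sire, dam, "F", year, fam, g))
            females[g].append((aid, fam))

    meta = pd.DataFrame(
        rows,
        columns=["animal", "sire", "dam", "sex", "birth_year",
                 "family", "generation"],
    )
    ped = Pedigree.from_dataframe(
        meta[["animal", "sire", "dam", "sex", "birth_year"]]
    )
    return ped, meta


def simulate_breeding_values(ped: Pedigree, true_G,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-animal coefficient vectors with cov(vec a) = A (x) G.

    Founders are MVN(0, G); an offspring is the parent average plus a
    Mendelian-sampling deviation with covariance d_i * G where
    d_i = 0.5 - 0.25 (F_sire + F_dam), with the usual unknown-parent
    adjustments.
    """
    G = np.asarray(true_G, dtype=float)
    q = G.shape[0]
    n = len(ped)
    a = np.zeros((n, q))
    if not np.any(G):
        return a
    L = np.linalg.cholesky(G + 1e-12 * np.eye(q))
    F = ped.inbreeding()
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        mean = np.zeros(q)
        if s >= 0 and d >= 0:
            mean = 0.5 * (a[s] + a[d])
            w = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            mean = 0.5 * a[s]
            w = 0.75 - 0.25 * F[s]
        elif d >= 0:
            mean = 0.5 * a[d]
            w = 0.75 - 0.25 * F[d]
        else:
            w = 1.0
        a[i] = mean + np.sqrt(w) * (L @ rng.standard_normal(q))
    return a


def _decode_litter(category: int, n_categories: int) -> int:
    # minimal count consistent with the category coding
    return int(category)


def simulate_records(ped: Pedigree, a: np.ndarray,
                     scenario: SimulationScenario,
                     rng: np.random.Generator) -> tuple:
    """Simulate lambing records (and the full latent truth) for all ewes.

    Returns (records DataFrame, truth DataFrame, p matrix, year-effects
    dict). The truth table contains every additive term of each record's
    liability, so residual = liability - sum(terms) reproduces the drawn
    residual exactly.
    """
    scen = scenario
    basis = LegendreBasis(order=scen.order)
    P = np.asarray(scen.true_P, dtype=float)
    q = P.shape[0]
    LP = (np.linalg.cholesky(P + 1e-12 * np.eye(q))
          if np.any(P) else np.zeros((q, q)))
    thresholds = np.asarray(scen.thresholds, dtype=float)
    tau = np.concatenate(([-np.inf], thresholds, [np.inf]))

    is_ewe = ped.sex == "F"
    ewe_idx = np.flatnonzero(is_ewe)
    year_effects: dict[int, float] = {}

    rec_rows, truth_rows = [], []
    p_mat = np.zeros((len(ewe_idx), q))
    for k, i in enumerate(ewe_idx):
        p_vec = LP @ rng.standard_normal(q)
        p_mat[k] = p_vec
        birth = int(ped.birth_year[i]) if np.isfinite(ped.birth_year[i]) else 0
        for t in range(1, 7):
            if t > 1 and rng.random() >= scen.parity_retention[t - 2]:
                break
            year = birth + 1 + (t - 1)
            if year not in year_effects:
                year_effects[year] = scen.year_sd * rng.standard_normal()
            m = int(rng.choice(3, p=_MONTH_PROBS))
            phi = basis.row(t)
            g_term = float(phi @ a[i])
            p_term = float(phi @ p_vec)
            f_term = float(phi @ np.asarray(scen.beta, dtype=float))
            sigma = np.sqrt(scen.true_resid[scen.class_of(t) - 1])
            e = sigma * rng.standard_normal()
            liab = (year_effects[year] + scen.month_effects[m]
                    + f_term + g_term + p_term + e)
            cat = int(np.searchsorted(tau, liab, side="left"))
            cat = min(max(cat, 1), scen.n_categories)
            rec_rows.append(
                (ped.ids[i], year, _MONTH_NAMES[m], t,
                 _decode_litter(cat, scen.n_categories))
            )
            truth_rows.append(
                (ped.ids[i], t, year, _MONTH_NAMES[m], liab, e,
                 year_effects[year], scen.month_effects[m],
                 f_term, g_term, p_term, cat)
            )
    records = pd.DataFrame(
        rec_rows, columns=["ewe", "year", "month", "parity", "litter_size"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["ewe", "parity", "year", "month", "liability", "residual",
                 "year_effect", "month_effect", "fixed_regression",
                 "genetic", "permanent_environment", "category"],
    )
    return records, truth, p_mat, year_effects


@dataclass
class SyntheticDataset:
    """A generated flock: inputs for the fitter plus the latent truth."""

    scenario: SimulationScenario
    pedigree: Pedigree
    records: pd.DataFrame
    truth: pd.DataFrame
    a: np.ndarray       # breeding-value coefficients, pedigree order
    p: np.ndarray       # permanent-environment coefficients, ewe order
    year_effects: dict

    def true_trajectory(self):
        """True per-parity variance components and h2/c2 under the scenario."""
        from .trajectory import params_from_components

        scen = self.scenario
        basis = LegendreBasis(order=scen.order)
        return params_from_components(
            scen.true_G, scen.true_P, scen.true_resid, basis,
            {t: scen.class_of(t) for t in range(1, 7)},
        )

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_file(outdir / "pedigree.csv")
        self.records.to_csv(outdir / "records.csv", index=False)
        self.truth.to_csv(outdir / "truth_records.csv", index=False)
        params = {
            "line": self.scenario.line,
            "seed": self.scenario.seed,
            "true_G": np.asarray(self.scenario.true_G).tolist(),
            "true_P": np.asarray(self.scenario.true_P).tolist(),
            "true_resid": list(self.scenario.true_resid),
            "thresholds": list(self.scenario.thresholds),
            "beta": np.asarray(self.scenario.beta).tolist(),
            "month_effects": list(self.scenario.month_effects),
            "year_effects": {
                str(k): v for k, v in sorted(self.year_effects.items())
            },
        }
        with open(outdir / "truth_params.json", "w") as fh:
            json.dump(params, fh, indent=2)
        return {
            "pedigree": str(outdir / "pedigree.csv"),
            "records": str(outdir / "records.csv"),
        }


def simulate_dataset(scenario: SimulationScenario,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate pedigree, breeding values and records in one call."""
    rng = np.random.default_rng(
        scenario.seed if seed is None else seed
    )
    ped, _meta = simulate_pedigree(scenario, rng)
    a = simulate_breeding_values(ped, scenario.true_G, rng)
    records, truth, p_mat, year_effects = simulate_records(
        ped, a, scenario, rng
    )
    return SyntheticDataset(scenario, ped, records, truth, a, p_mat,
                            year_effects)
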