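"""Synthetic phosphoproteome compendia with known ground truth.

The generator emulates the statistical structure of a multi-study
phosphoproteomics compendium so every pipeline stage can be tested without
external data:

* **Multi-study sparsity.**  Conditions are partitioned into studies; each
  study observes each site with a site-specific detection propensity.
  Curated sites (kinase substrates and complex subunit sites, the
  well-studied part of a real compendium) draw their propensity from a
  high-detection Beta; the remaining background sites draw from a sparse
  Beta tuned so that about half of the observed background sites appear in
  a single study.
* **Substrate-mediated fold-change propagation.**  Per condition, a sparse
  set of kinases carries a true activity; substrate site values are the
  sum of their kinases' activities (with optional sign flips emulating
  inhibitory phosphosites) plus Gaussian noise.
* **Complex-coordinated regulation.**  A fraction of complexes is coupled
  to a kinase; when that kinase is regulated, every site on the complex's
  subunits receives a shared shift proportional to the activity.
* **Motif-bearing flanks.**  Each kinase has a true position-weight matrix
  with a few informative positions; its substrates' flanking sequences are
  sampled from it, background flanks from the uniform distribution.

The default parameters are the packaged desk-scale fixture: 40 kinases ×
60 conditions × 4,000 sites, 20 substrates per kinase, activity SD twice
the noise SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as pio
from .ksea import child_rng
from .types import (
    ComplexCatalog,
    FlankTable,
    KinaseSubstrateSets,
    PhosphoCompendium,
    SiteID,
)
from .effectors import AMINO_ACIDS

__all__ = ["SimulationParams", "GroundTruth", "simulate_truth",
           "simulate_compendium", "simulate_flanks", "export_fixture",
           "default_fixture"]

_RESIDUES = "STY"


@dataclass
class SimulationParams:
    """Tunable knobs of the synthetic compendium; defaults are the packaged fixture."""

    n_kinases: int = 40
    n_conditions: int = 60
    n_sites: int = 4000
    n_studies: int = 6
    sites_per_protein: int = 5
    substrates_per_kinase: int = 20
    revealed_fraction: float = 0.8
    substrate_overlap: float = 0.0
    generalist_fraction: float = 0.2
    pi_specialist: float = 0.15
    pi_generalist: float = 0.5
    sigma_activity: float = 2.0
    sigma_noise: float = 1.0
    inhibitory_fraction: float = 0.0
    heavy_tailed_noise: bool = False
    n_complexes: int = 30
    complex_size_min: int = 4
    complex_size_max: int = 8
    coupled_fraction: float = 0.5
    coupling_strength: float = 0.8
    # detection propensities: curated sites (substrates, complex subunits)
    # versus background; background tuned for ~52% single-study sites
    detection_curated: tuple[float, float] = (5.0, 2.0)
    detection_background: tuple[float, float] = (0.35, 3.0)
    single_study_target: float = 0.52
    tech_replicate_fraction: float = 0.2
    n_tech_replicates: int = 2
    tech_noise: float = 0.1
    n_bio_replicates: int = 1
    multiphospho_rate: float = 0.05
    flank_window: int = 7
    motif_informative_positions: int = 4
    motif_concentration: float = 0.7


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream recovery checks."""

    params: SimulationParams
    proteins: list[str]
    sites: list[SiteID]
    kinases: list[str]
    substrate_sets: dict[str, set[SiteID]]
    substrate_signs: dict[tuple[str, str], int]
    revealed_sets: KinaseSubstrateSets
    activity: pd.DataFrame
    generalists: set[str]
    catalog: ComplexCatalog
    couplings: set[tuple[str, str]]
    motifs: dict[str, np.ndarray]
    study_of_condition: dict[str, str]
    detection: pd.Series
    curated_tokens: set[str] = field(default_factory=set)

    @property
    def conditions(self) -> list[str]:
        return list(self.activity.columns)


def simulate_truth(
    params: SimulationParams | None = None, seed: int = 0
) -> GroundTruth:
    """Draw the latent state of a synthetic compendium.

    Kinase identifiers are protein accessions (the first proteins), so the
    kinase–kinase network derived from substrate sets is non-trivial.
    A designated generalist fraction of kinases is regulated in more
    conditions than the specialist rest; every condition ends up with at
    least one regulated kinase.
    """
    p = params or SimulationParams()
    rng = child_rng(seed, "truth")

    n_proteins = -(-p.n_sites // p.sites_per_protein)
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    sites: list[SiteID] = []
    taken_positions: dict[str, set[int]] = {}
    for i in range(p.n_sites):
        prot = proteins[i // p.sites_per_protein]
        used = taken_positions.setdefault(prot, set())
        while True:
            pos = int(rng.integers(1, 2000))
            if pos not in used:
                used.add(pos)
                break
        residue = _RESIDUES[rng.choice(3, p=[0.6, 0.3, 0.1])]
        sites.append(SiteID(prot, residue, pos))
    site_by_protein: dict[str, list[SiteID]] = {}
    for s in sites:
        site_by_protein.setdefault(s.protein, []).append(s)

    kinases = proteins[: p.n_kinases]
    conditions = [f"c{i + 1:03d}" for i in range(p.n_conditions)]
    studies = [f"study{j + 1}" for j in range(p.n_studies)]
    study_of_condition = {
        c: studies[i * p.n_studies // p.n_conditions]
        for i, c in enumerate(conditions)
    }

    # complexes over non-kinase proteins
    complex_pool = proteins[p.n_kinases:]
    catalog_map: dict[str, frozenset[str]] = {}
    used_proteins: set[str] = set()
    for i in range(p.n_complexes):
        size = int(rng.integers(p.complex_size_min, p.complex_size_max + 1))
        free = [x for x in complex_pool if x not in used_proteins]
        if len(free) < p.complex_size_min:
            break  # protein pool exhausted at small scales
        members = rng.choice(free, size=min(size, len(free)), replace=False)
        used_proteins.update(members)
        catalog_map[f"CPX{i + 1:03d}"] = frozenset(members.tolist())
    catalog = ComplexCatalog(catalog_map)

    n_coupled = int(round(p.coupled_fraction * p.n_complexes))
    coupled_complexes = list(rng.choice(sorted(catalog_map), size=n_coupled, replace=False))
    couplings = {
        (kinases[int(rng.integers(0, p.n_kinases))], cid) for cid in coupled_complexes
    }

    # substrate sets: drawn from background proteins; coupled complexes
    # contribute one substrate site each so known-substrate validation of
    # couplings has signal
    complex_proteins = used_proteins
    background_sites = [s for s in sites if s.protein not in complex_proteins]
    background_sites = [background_sites[i] for i in rng.permutation(len(background_sites))]
    substrate_sets: dict[str, set[SiteID]] = {k: set() for k in kinases}
    cursor = 0
    assigned: list[SiteID] = []
    for k in kinases:
        need = p.substrates_per_kinase
        chosen: set[SiteID] = set()
        for kk, cid in sorted(couplings):
            if kk == k:
                cps = [
                    s for prot in sorted(catalog_map[cid])
                    for s in site_by_protein[prot]
                ]
                chosen.add(cps[int(rng.integers(0, len(cps)))])
        n_overlap = int(round(p.substrate_overlap * need))
        if assigned and n_overlap:
            take = rng.choice(len(assigned), size=min(n_overlap, len(assigned)),
                              replace=False)
            chosen.update(assigned[i] for i in take)
        while len(chosen) < need and cursor < len(background_sites):
            chosen.add(background_sites[cursor])
            cursor += 1
        if len(chosen) < need:
            # small scales can exhaust the non-complex pool; fall back to
            # any not-yet-assigned site
            taken = {s for subs in substrate_sets.values() for s in subs} | chosen
            spare = [s for s in sites if s not in taken]
            spare = [spare[i] for i in rng.permutation(len(spare))]
            chosen.update(spare[: need - len(chosen)])
        if not chosen:
            raise ValueError("not enough sites to assign kinase substrates")
        substrate_sets[k] = chosen
        assigned.extend(chosen)

    substrate_signs: dict[tuple[str, str], int] = {}
    for k in sorted(substrate_sets):
        for s in sorted(substrate_sets[k]):
            flip = rng.random() < p.inhibitory_fraction
            substrate_signs[(k, str(s))] = -1 if flip else 1

    # revealed (known) edges drive the inference; the rest is held out
    revealed: dict[str, set[SiteID]] = {}
    for k in sorted(substrate_sets):
        subs_sorted = sorted(substrate_sets[k])
        n_rev = max(1, int(round(p.revealed_fraction * len(subs_sorted))))
        idx = rng.choice(len(subs_sorted), size=n_rev, replace=False)
        revealed[k] = {subs_sorted[i] for i in idx}
    revealed_sets = KinaseSubstrateSets(revealed)

    # sparse activities with a generalist/specialist contrast
    n_gen = int(round(p.generalist_fraction * p.n_kinases))
    generalists = set(rng.choice(kinases, size=n_gen, replace=False).tolist())
    A = np.zeros((p.n_kinases, p.n_conditions))
    for i, k in enumerate(kinases):
        pi = p.pi_generalist if k in generalists else p.pi_specialist
        mask = rng.random(p.n_conditions) < pi
        A[i, mask] = rng.normal(0.0, p.sigma_activity, size=int(mask.sum()))
    for j in range(p.n_conditions):
        if not A[:, j].any():
            i = int(rng.integers(0, p.n_kinases))
            A[i, j] = rng.normal(0.0, p.sigma_activity)
            while A[i, j] == 0.0:
                A[i, j] = rng.normal(0.0, p.sigma_activity)
    activity = pd.DataFrame(A, index=kinases, columns=conditions)

    # true motifs: mostly uniform with a few informative positions
    motifs: dict[str, np.ndarray] = {}
    width = 2 * p.flank_window + 1
    off_center = [i for i in range(width) if i != p.flank_window]
    for k in kinases:
        pwm = np.full((width, len(AMINO_ACIDS)), 1.0 / len(AMINO_ACIDS))
        info_pos = rng.choice(off_center, size=p.motif_informative_positions,
                              replace=False)
        for pos in info_pos:
            aa = int(rng.integers(0, len(AMINO_ACIDS)))
            pwm[pos] = (1.0 - p.motif_concentration) / (len(AMINO_ACIDS) - 1)
            pwm[pos, aa] = p.motif_concentration
        motifs[k] = pwm

    # detection propensities
    curated_tokens = {
        str(s) for subs in substrate_sets.values() for s in subs
    } | {
        str(s) for prot in complex_proteins for s in site_by_protein[prot]
    }
    a_c, b_c = p.detection_curated
    a_b, b_b = p.detection_background
    prop = {}
    for s in sites:
        tok = str(s)
        if tok in curated_tokens:
            prop[tok] = rng.beta(a_c, b_c)
        else:
            prop[tok] = rng.beta(a_b, b_b)
    detection = pd.Series(prop)

    return GroundTruth(
        params=p,
        proteins=proteins,
        sites=sites,
        kinases=kinases,
        substrate_sets=substrate_sets,
        substrate_signs=substrate_signs,
        revealed_sets=revealed_sets,
        activity=activity,
        generalists=generalists,
        catalog=catalog,
        couplings=couplings,
        motifs=motifs,
        study_of_condition=study_of_condition,
        detection=detection,
        curated_tokens=curated_tokens,
    )


def _signal_matrix(truth: GroundTruth) -> pd.DataFrame:
    """Noise-free site × condition signal implied by the ground truth."""
    p = truth.params
    tokens = [str(s) for s in truth.sites]
    Q = pd.DataFrame(0.0, index=tokens, columns=truth.conditions)
    A = truth.activity
    for k in sorted(truth.substrate_sets):
        ak = A.loc[k].to_numpy()
        for s in sorted(truth.substrate_sets[k]):
            w = truth.substrate_signs[(k, str(s))]
            Q.loc[str(s)] += w * ak
    site_by_protein: dict[str, list[str]] = {}
    for s in truth.sites:
        site_by_protein.setdefault(s.protein, []).append(str(s))
    for k, cid in sorted(truth.couplings):
        ak = A.loc[k].to_numpy()
        shift = p.coupling_strength * ak
        for prot in sorted(truth.catalog.complexes[cid]):
            for tok in site_by_protein.get(prot, ()):
                Q.loc[tok] += shift
    return Q


def simulate_compendium(truth: GroundTruth, seed: int = 0) -> PhosphoCompendium:
    """Emit the long-format record table implied by the ground truth.

    Values are signal + noise; each study observes each site according to
    its detection propensity; a configurable fraction of conditions gets
    technical replicates, and multiphosphorylated decoy peptides are
    injected to exercise the monophospho filter.
    """
    p = truth.params
    rng = child_rng(seed, "compendium")
    Q = _signal_matrix(truth)
    tokens = Q.index.to_numpy()
    n_sites = len(tokens)

    q = truth.detection[tokens].to_numpy()
    studies = sorted(set(truth.study_of_condition.values()))
    observed = {s: rng.random(n_sites) < q for s in studies}

    tech_conditions = set(
        rng.choice(
            truth.conditions,
            size=int(round(p.tech_replicate_fraction * len(truth.conditions))),
            replace=False,
        ).tolist()
    )

    site_objs = {str(s): s for s in truth.sites}
    sites_of_protein: dict[str, list[SiteID]] = {}
    for s in truth.sites:
        sites_of_protein.setdefault(s.protein, []).append(s)
    frames = []
    for cond in truth.conditions:
        study = truth.study_of_condition[cond]
        mask = observed[study]
        toks = tokens[mask]
        base = Q.loc[toks, cond].to_numpy()
        if p.heavy_tailed_noise:
            noise = rng.standard_t(3, size=len(toks)) * p.sigma_noise
        else:
            noise = rng.normal(0.0, p.sigma_noise, size=len(toks))
        values = base + noise

        reps: list[tuple[int, str, np.ndarray]] = []
        if cond in tech_conditions and p.n_tech_replicates > 1:
            for r in range(1, p.n_tech_replicates + 1):
                jitter = rng.normal(0.0, p.tech_noise, size=len(toks))
                reps.append((r, "technical", values + jitter))
        elif p.n_bio_replicates > 1:
            for r in range(1, p.n_bio_replicates + 1):
                extra = rng.normal(0.0, p.sigma_noise, size=len(toks))
                reps.append((r, "biological", base + extra))
        else:
            reps.append((1, "biological", values))

        for rep, kind, vals in reps:
            objs = [site_objs[t] for t in toks]
            frames.append(pd.DataFrame({
                "study": study,
                "condition": cond,
                "replicate": rep,
                "replicate_kind": kind,
                "protein": [o.protein for o in objs],
                "residue": [o.residue for o in objs],
                "position": [o.position for o in objs],
                "mod_key": [f"{o.protein}:{o.residue}{o.position}" for o in objs],
                "log2_ratio": vals,
            }))

        # multiphosphorylated decoys (filtered by preprocessing)
        n_decoys = int(round(p.multiphospho_rate * len(toks)))
        if n_decoys:
            idx = rng.choice(len(truth.sites), size=n_decoys, replace=False)
            rows = []
            for i in idx:
                s1 = truth.sites[i]
                partners = [x for x in sites_of_protein[s1.protein] if x != s1]
                s2 = partners[int(rng.integers(0, len(partners)))]
                first, second = sorted([s1, s2], key=lambda s: s.position)
                rows.append({
                    "study": study, "condition": cond, "replicate": 1,
                    "replicate_kind": "biological",
                    "protein": first.protein, "residue": first.residue,
                    "position": first.position,
                    "mod_key": (f"{first.protein}:{first.residue}{first.position}"
                                f"+{second.residue}{second.position}"),
                    "log2_ratio": float(rng.normal(0.0, 1.0)),
                })
            frames.append(pd.DataFrame(rows))

    records = pd.concat(frames, ignore_index=True)
    return PhosphoCompendium(records)


def simulate_flanks(truth: GroundTruth, seed: int = 0) -> FlankTable:
    """Flanking sequences: substrates from their kinase's motif, rest uniform."""
    p = truth.params
    rng = child_rng(seed, "flanks")
    width = 2 * p.flank_window + 1
    aa = np.array(list(AMINO_ACIDS))
    owner: dict[str, str] = {}
    for k in sorted(truth.substrate_sets):
        for s in truth.substrate_sets[k]:
            owner.setdefault(str(s), k)
    flanks: dict[SiteID, str] = {}
    for s in truth.sites:
        tok = str(s)
        k = owner.get(tok)
        chars = []
        for pos in range(width):
            if pos == p.flank_window:
                chars.append(s.residue)
            elif k is None:
                chars.append(str(rng.choice(aa)))
            else:
                chars.append(str(rng.choice(aa, p=truth.motifs[k][pos])))
        flanks[s] = "".join(chars)
    return FlankTable(flanks)


def export_fixture(truth: GroundTruth, compendium: PhosphoCompendium,
                   flanks: FlankTable, out_dir) -> dict:
    """Write the fixture files (compendium TSV, GMT, complexes, flanks, truth JSON)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_compendium(compendium, out / "compendium.tsv")
    pio.write_kinase_sets_gmt(truth.revealed_sets, out / "kinase_sets.gmt")
    pio.write_complexes(truth.catalog, out / "complexes.tsv")
    pio.write_flanks(flanks, out / "flanks.tsv")
    truth_json = {
        "kinases": truth.kinases,
        "conditions": truth.conditions,
        "generalists": sorted(truth.generalists),
        "couplings": sorted(list(c) for c in truth.couplings),
        "activity": truth.activity.to_dict(orient="index"),
        "substrate_sets": {
            k: sorted(str(s) for s in subs)
            for k, subs in truth.substrate_sets.items()
        },
        "study_of_condition": truth.study_of_condition,
        "params": asdict(truth.params),
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=1)
    return {"dir": str(out), "n_records": len(compendium)}


def default_fixture(seed: int = 0, params: SimulationParams | None = None):
    """Convenience: (truth, compendium, flanks) at the packaged defaults."""
    truth = simulate_truth(params, seed=seed)
    compendium = simulate_compendium(truth, seed=seed)
    flanks = simulate_flanks(truth, seed=seed)
    return truth, compendium, flanks
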