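"""Round-trip evaluation experiments on synthetic data.

Planted-truth recovery rates for the two inference stages: precursor mining
on synthetic genomes, and ring-topology inference from simulated partial
desulfurization spectra.  Both are deterministic given their seeds.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .chem import ModificationSet
from .mining import filter_precursors, find_orfs, select_adjacent
from .ms1 import PeptideSpecies
from .rings import (
    RingTopology,
    desulfurize,
    infer_topology_from_desulfurization,
)
from .simulate import (
    GenomeSimSpec,
    SpectrumSimSpec,
    generate_genome,
    generate_ms2,
    generate_ms2_from_fragments,
    random_core,
)

__all__ = [
    "precursor_recovery_rate",
    "random_two_ring_topology",
    "topology_recovery_trial",
    "topology_recovery_rate",
]


def precursor_recovery_rate(
    n_genomes: int = 5,
    seed: int = 0,
    n_true: int = 2,
    decoy_clauses: Tuple[str, ...] = ("too_long", "no_cys", "no_st"),
) -> float:
    """Fraction of planted filter-satisfying precursors recovered by mining.

    Genomes are noiseless in the relevant sense (planting is exact); decoy
    ORFs violating one filter clause each are present and must not pass.
    A decoy passing the filter would be a bug in the generator, not the
    miner, and raises.
    """
    recovered = 0
    total = 0
    for g in range(n_genomes):
        spec = GenomeSimSpec(
            seed=seed + g, n_true=n_true, decoy_clauses=decoy_clauses
        )
        genome, truth = generate_genome(spec)
        anchor = genome.features_of_type("lanM")[0]
        cands = filter_precursors(
            select_adjacent(find_orfs(genome, anchor), k=10)
        )
        mined = {c.aa_sequence for c in cands}
        planted = set(truth[truth["class"] == "true"]["peptide"])
        decoys = set(truth[truth["class"] == "decoy"]["peptide"])
        if mined & decoys:
            raise AssertionError("a clause-violating decoy passed the filter")
        total += len(planted)
        recovered += len(planted & mined)
    return recovered / total


def random_two_ring_topology(
    core: str, rng: np.random.Generator
) -> RingTopology:
    """A random injective 2-link pairing of Cys acceptors and S/T donors."""
    cys = [i + 1 for i, aa in enumerate(core) if aa == "C"]
    donors = [i + 1 for i, aa in enumerate(core) if aa in "ST"]
    accs = sorted(rng.choice(cys, size=2, replace=False).tolist())
    dons = rng.choice(donors, size=2, replace=False).tolist()
    return RingTopology(tuple(sorted(zip(dons, accs))), core)


def topology_recovery_trial(
    seed: int,
    core_length_range: Tuple[int, int] = (10, 20),
    jitter_ppm_sd: float = 5.0,
    noise_fraction: float = 0.2,
    tol_ppm: float = 10.0,
    charges: Sequence[int] = (1, 2),
) -> bool:
    """One seeded round trip: plant a 2-ring truth, simulate, infer, compare.

    Simulates the parent MS/MS spectrum plus one partial-desulfurization
    spectrum per ring (reagent D, deuteration placement drawn at random),
    then checks whether joint inference returns the planted crosslink set.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(core_length_range[0], core_length_range[1] + 1))
    core = random_core(rng, length, n_cys=2, n_st=3)
    truth = random_two_ring_topology(core, rng)
    species = PeptideSpecies(core, ModificationSet(n_dehydration=2))

    sim = lambda s: SpectrumSimSpec(
        seed=s, jitter_ppm_sd=jitter_ppm_sd, noise_fraction=noise_fraction,
        charges=tuple(charges),
    )
    parent = generate_ms2(species, truth, sim(seed * 7 + 1))
    product_spectra = []
    for j, link in enumerate(truth.crosslinks):
        product = desulfurize(species, truth, [link], reagent="D")
        variant = product.variants[int(rng.integers(len(product.variants)))]
        frags = product.fragments(variant, charges=charges)
        product_spectra.append(
            generate_ms2_from_fragments(frags, sim(seed * 7 + 2 + j))
        )
    result = infer_topology_from_desulfurization(
        parent,
        product_spectra,
        species,
        n_links=2,
        tol_ppm=tol_ppm,
        charges=charges,
    )
    return (
        result.topology is not None
        and result.topology.crosslinks == truth.crosslinks
    )


def topology_recovery_rate(
    n_trials: int = 20,
    seed: int = 0,
    **trial_kwargs,
) -> float:
    """Fraction of seeded noisy simulations whose topology is recovered."""
    wins = sum(
        topology_recovery_trial(seed * 1000 + t, **trial_kwargs)
        for t in range(n_trials)
    )
    return wins / n_trials
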