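"""Three-population divergence-plus-pulse-admixture coalescent simulator.

The demographic scenario: an ancestral population splits at ``t_split``
generations ago into the native lineage (SFL) and the donor lineage (WCU);
at ``t_admix`` generations ago the hybrid population (MIA) is founded by a
single admixture pulse drawing a fraction ``r_admix`` of its lineages from
WCU and the rest from SFL.  Microsatellite loci evolve under a stepwise /
generalised stepwise mutation model on independent genealogies; one
maternal haploid locus records, for every MIA individual, the parental
population its maternal lineage occupied immediately before the pulse
(backward in time: immediately after the jump) — the simulated analogue of
an mtDNA clade assignment.

All times are in generations and population sizes are effective diploid
sizes.  The continuous-time (Kingman) approximation is used throughout;
with the effective sizes this model targets (hundreds to thousands) the
discrete-generation correction is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .io import GenotypeTable, PopulationMap

__all__ = [
    "DemographicModel",
    "Genealogy",
    "SimulatedDataset",
    "simulate_genealogy",
    "drop_microsat_mutations",
    "simulate_dataset",
]

DEFAULT_LABELS = ("SFL", "MIA", "WCU")


@dataclass(frozen=True)
class DemographicModel:
    """Parameters of the divergence-plus-pulse-admixture scenario.

    Sizes are effective diploid sizes; times are generations before
    present; ``r_admix`` is the proportion of the hybrid population's
    founding lineages drawn from the donor (WCU) side; ``mu`` is the
    per-locus per-generation microsatellite mutation rate and ``gsm_p``
    the probability that a mutation is a single repeat step (1.0 gives the
    strict stepwise model).  ``n_anc`` defaults to the donor-lineage size,
    the paraphyletic source of the native lineage.
    """

    n_sfl: float
    n_mia: float
    n_wcu: float
    t_admix: float
    r_admix: float
    t_split: float
    n_anc: float | None = None
    mu: float = 5e-4
    gsm_p: float = 1.0
    root_state: int = 100

    def __post_init__(self) -> None:
        if min(self.n_sfl, self.n_mia, self.n_wcu) < 2:
            raise ValueError("effective sizes must be >= 2")
        if not (0 < self.t_admix < self.t_split):
            raise ValueError("require 0 < t_admix < t_split")
        if not (0 <= self.r_admix <= 1):
            raise ValueError("r_admix must lie in [0, 1]")
        if not (0 <= self.mu < 1):
            raise ValueError("mu must lie in [0, 1)")
        if not (0 < self.gsm_p <= 1):
            raise ValueError("gsm_p must lie in (0, 1]")

    @property
    def anc_size(self) -> float:
        return self.n_wcu if self.n_anc is None else self.n_anc

    def sizes(self) -> np.ndarray:
        return np.array([self.n_sfl, self.n_mia, self.n_wcu], float)


@dataclass
class Genealogy:
    """A single-locus genealogy over the sampled gene copies.

    Nodes ``0..n_tips-1`` are tips; internal node ids increase with
    coalescence time; the root's parent is -1.  ``origin`` holds, for the
    lineages alive at the admixture pulse, the population code they jumped
    to (backward in time), and -1 elsewhere.
    """

    parent: np.ndarray
    node_time: np.ndarray
    tip_pop: np.ndarray          # population code per tip (0=SFL,1=MIA,2=WCU)
    origin: np.ndarray
    t_admix: float
    ploidy: str                  # "diploid-autosomal" | "haploid-maternal"

    @property
    def n_tips(self) -> int:
        return len(self.tip_pop)

    def branch_length(self, v: int) -> float:
        if self.parent[v] == -1:
            return 0.0
        child_t = self.node_time[v] if v >= self.n_tips else 0.0
        return float(self.node_time[self.parent[v]] - child_t)

    def tip_origin_at_admixture(self) -> np.ndarray:
        """Post-pulse population code of each tip's ancestral lineage."""
        return _kernels.origin_at_admixture(
            self.parent, self.node_time, self.origin, self.n_tips, self.t_admix
        )

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])


@dataclass
class SimulatedDataset:
    """Genotypes plus per-individual maternal-lineage origins for MIA."""

    genotypes: GenotypeTable
    mtdna_origin: dict[str, str]   # MIA individual -> "SFL" | "WCU"
    model: DemographicModel

    def donor_mtdna_fraction(self) -> float:
        vals = list(self.mtdna_origin.values())
        return sum(v == "WCU" for v in vals) / len(vals)


def _sample_codes(samples: PopulationMap, copies_per_ind: int) -> np.ndarray:
    codes = []
    for code, label in enumerate(DEFAULT_LABELS):
        n = samples.sizes.get(label, 0)
        codes.extend([code] * (n * copies_per_ind))
    if not codes:
        raise ValueError(
            f"sample map must use the population labels {DEFAULT_LABELS}"
        )
    return np.array(codes, np.int64)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogy(model: DemographicModel, samples: PopulationMap,
                       ploidy: str = "diploid-autosomal",
                       rng: np.random.Generator | int | None = None) -> Genealogy:
    """Simulate one genealogy under the demographic scenario.

    ``ploidy`` selects the gene-copy numbers: two copies per diploid
    individual for autosomal loci (copy number 2N per population), one
    maternally inherited copy per individual for the mtDNA locus (copy
    number N/2, females only).
    """
    if ploidy not in ("diploid-autosomal", "haploid-maternal"):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    rng = np.random.default_rng(rng)
    diploid = ploidy == "diploid-autosomal"
    pop0 = _sample_codes(samples, 2 if diploid else 1)
    factor = 2.0 if diploid else 0.5
    copies = factor * model.sizes()
    anc = factor * model.anc_size
    parent, ntime, origin = _kernels.coalesce_kernel(
        pop0, copies, float(model.t_admix), float(model.r_admix),
        float(model.t_split), float(anc), _sub_seed(rng),
    )
    return Genealogy(parent, ntime, pop0, origin, float(model.t_admix), ploidy)


def drop_microsat_mutations(genealogy: Genealogy, model: DemographicModel,
                            rng: np.random.Generator | int | None = None,
                            ) -> np.ndarray:
    """Allele states (repeat units) at the tips of one genealogy.

    Mutations are Poisson on branches at rate ``model.mu`` per generation;
    each is a fair-signed step of one repeat unit with probability
    ``model.gsm_p``, else a geometric multi-step jump with mean two steps.
    The root carries ``model.root_state``.
    """
    rng = np.random.default_rng(rng)
    return _kernels.mutate_kernel(
        genealogy.parent, genealogy.node_time, genealogy.n_tips,
        float(model.mu), float(model.gsm_p), int(model.root_state),
        _sub_seed(rng),
    )


def simulate_dataset(model: DemographicModel, samples: PopulationMap,
                     n_loci: int = 18,
                     rng: np.random.Generator | int | None = None,
                     ) -> SimulatedDataset:
    """Simulate a full study-shaped dataset.

    ``n_loci`` independent autosomal genealogies produce a
    :class:`GenotypeTable` (the two gene copies of an individual are the
    consecutive sampled copies of that individual); one maternal haploid
    genealogy yields each MIA individual's pre-admixture maternal origin.
    Allele states are shifted to stay positive if a random walk wanders
    at or below zero.
    """
    rng = np.random.default_rng(rng)
    labels = [l for l in DEFAULT_LABELS if samples.sizes.get(l, 0) > 0]
    n_ind = sum(samples.sizes[l] for l in labels)
    allele_mat = np.empty((n_ind, n_loci, 2), np.int32)
    for j in range(n_loci):
        g = simulate_genealogy(model, samples, "diploid-autosomal", rng)
        tips = drop_microsat_mutations(g, model, rng)
        if tips.min() <= 0:
            tips = tips - tips.min() + 1
        allele_mat[:, j, :] = tips.reshape(-1, 2)
    individuals, pops = [], []
    for label in labels:
        for i in range(samples.sizes[label]):
            individuals.append(f"{label}{i + 1:03d}")
            pops.append(label)
    table = GenotypeTable(individuals, pops, [f"L{j + 1:02d}" for j in range(n_loci)],
                          allele_mat)
    mt_origin: dict[str, str] = {}
    if samples.sizes.get("MIA", 0) > 0:
        gm = simulate_genealogy(model, samples, "haploid-maternal", rng)
        origins = gm.tip_origin_at_admixture()
        mia_tips = np.flatnonzero(gm.tip_pop == 1)
        mia_names = [ind for ind, p in zip(individuals, pops) if p == "MIA"]
        for name, tip in zip(mia_names, mia_tips):
            mt_origin[name] = "WCU" if origins[tip] == 2 else "SFL"
    return SimulatedDataset(table, mt_origin, model)
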