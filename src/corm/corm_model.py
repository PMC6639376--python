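"""Reaction network for a two-substrate, allosterically regulated cyclooxygenase.

The enzyme is modelled as a functional heterodimer: one catalytic site and one
allosteric site, each of which is empty or occupied by arachidonic acid (AA)
or 2-arachidonoylglycerol (2-AG, species id ``AG``).  The 3 x 3 occupancy grid
yields nine enzyme states.  Together with the two free substrates and the two
products -- prostaglandin (``PG``, from AA) and prostaglandin glycerol
(``PGG``, from 2-AG) -- the network holds 13 species.

Reactions are mass-action and unidirectional:

* 12 binding reactions (enzyme state + free substrate -> complex),
* 12 unbinding reactions (their exact reverses),
* 5 turnover reactions.  Every state with an occupied catalytic site is
  turned over except ``E(cat=AG,allo=AG)``: the doubly 2-AG-bound complex is
  catalytically dead (substrate-dependent inhibition).  Turnover releases the
  product of the catalytic ligand and regenerates the enzyme state with an
  empty catalytic site and unchanged allosteric occupancy.

That counting gives 29 reactions.  Units are uM and seconds throughout;
bimolecular rate constants are in 1/(uM s), unimolecular in 1/s.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "SiteOccupancy",
    "EnzymeState",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "MissingParameterError",
    "build_corm",
    "rate_law",
    "binding_cycles",
    "network_to_json",
    "network_from_json",
    "FREE_ENZYME_ID",
    "SUBSTRATE_ID",
    "PRODUCT_ID",
]


class SiteOccupancy(enum.Enum):
    """Occupancy of one enzyme site: empty, or holding AA or 2-AG."""

    EMPTY = "EMPTY"
    AA = "AA"
    AG = "AG"


#: Site occupancies in canonical order (used for deterministic enumeration).
OCCUPANCIES: tuple[SiteOccupancy, ...] = (
    SiteOccupancy.EMPTY,
    SiteOccupancy.AA,
    SiteOccupancy.AG,
)

#: The two ligands that can occupy a site.
LIGANDS: tuple[SiteOccupancy, ...] = (SiteOccupancy.AA, SiteOccupancy.AG)

#: Free-substrate species id for each ligand.
SUBSTRATE_ID: dict[SiteOccupancy, str] = {
    SiteOccupancy.AA: "AA",
    SiteOccupancy.AG: "AG",
}

#: Product species id released by turnover of each catalytic ligand.
PRODUCT_ID: dict[SiteOccupancy, str] = {
    SiteOccupancy.AA: "PG",
    SiteOccupancy.AG: "PGG",
}

FREE_ENZYME_ID = "E(cat=EMPTY,allo=EMPTY)"


class MissingParameterError(KeyError):
    """A reaction references a rate-constant name absent from the parameter set."""


@dataclass(frozen=True)
class EnzymeState:
    """Joint occupancy of the catalytic and allosteric sites."""

    cat: SiteOccupancy
    allo: SiteOccupancy

    @property
    def species_id(self) -> str:
        return f"E(cat={self.cat.value},allo={self.allo.value})"

    @property
    def is_free(self) -> bool:
        return self.cat is SiteOccupancy.EMPTY and self.allo is SiteOccupancy.EMPTY


#: The catalytically dead state: 2-AG in both sites, never turned over.
DEAD_STATE = EnzymeState(SiteOccupancy.AG, SiteOccupancy.AG)


@dataclass(frozen=True)
class Species:
    """One chemical species: an enzyme state, a free substrate, or a product."""

    id: str
    role: str  # "enzyme_state" | "substrate" | "product"
    state: EnzymeState | None = None

    def __post_init__(self) -> None:
        if self.role not in ("enzyme_state", "substrate", "product"):
            raise ValueError(f"unknown species role {self.role!r}")
        if (self.role == "enzyme_state") != (self.state is not None):
            raise ValueError("state must be set exactly for enzyme_state species")


@dataclass(frozen=True)
class Reaction:
    """A unidirectional mass-action reaction.

    ``reactants`` and ``products`` are tuples of ``(species_id, count)``;
    every reaction here has unit stoichiometric counts.  ``rate_constant_ref``
    names the parameter applied by :func:`rate_law`.
    """

    id: str
    kind: str  # "binding" | "unbinding" | "turnover"
    site: str  # "catalytic" | "allosteric" | "none"
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant_ref: str

    def __post_init__(self) -> None:
        if self.kind not in ("binding", "unbinding", "turnover"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.site not in ("catalytic", "allosteric", "none"):
            raise ValueError(f"unknown reaction site {self.site!r}")


@dataclass(frozen=True)
class ReactionNetwork:
    """An explicit, ordered list of species and unidirectional reactions."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]

    def species_by_id(self, species_id: str) -> Species:
        for sp in self.species:
            if sp.id == species_id:
                return sp
        raise KeyError(species_id)

    def reaction_by_id(self, reaction_id: str) -> Reaction:
        for rx in self.reactions:
            if rx.id == reaction_id:
                return rx
        raise KeyError(reaction_id)

    @property
    def enzyme_state_ids(self) -> tuple[str, ...]:
        return tuple(sp.id for sp in self.species if sp.role == "enzyme_state")

    @property
    def complex_ids(self) -> tuple[str, ...]:
        """Enzyme states with at least one occupied site (8 complexes)."""
        return tuple(
            sp.id
            for sp in self.species
            if sp.role == "enzyme_state" and sp.state is not None and not sp.state.is_free
        )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(rx.rate_constant_ref for rx in self.reactions)

    def reverse_of(self, reaction_id: str) -> str:
        """Id of the unbinding partner of a binding reaction, and vice versa."""
        if reaction_id.startswith("bind_"):
            return "unbind_" + reaction_id[len("bind_"):]
        if reaction_id.startswith("unbind_"):
            return "bind_" + reaction_id[len("unbind_"):]
        raise ValueError(f"{reaction_id!r} is not part of a reversible pair")


def _binding_suffix(site: str, ligand: SiteOccupancy, other: SiteOccupancy) -> str:
    if site == "catalytic":
        return f"cat_{ligand.value}__allo_{other.value}"
    return f"allo_{ligand.value}__cat_{other.value}"


def build_corm() -> ReactionNetwork:
    """Construct the canonical 13-species, 29-reaction network.

    Species order: the nine enzyme states in (cat, allo) lexicographic order
    over (EMPTY, AA, AG), then AA, AG, PG, PGG.  Reaction order: all binding
    reactions, all unbinding reactions, all turnover reactions, each block in
    deterministic site/ligand order.  Names are stable across runs so that
    downstream reports are comparable.
    """
    species: list[Species] = []
    for cat in OCCUPANCIES:
        for allo in OCCUPANCIES:
            state = EnzymeState(cat, allo)
            species.append(Species(state.species_id, "enzyme_state", state))
    species.append(Species("AA", "substrate"))
    species.append(Species("AG", "substrate"))
    species.append(Species("PG", "product"))
    species.append(Species("PGG", "product"))

    bindings: list[Reaction] = []
    unbindings: list[Reaction] = []

    def add_pair(site: str, ligand: SiteOccupancy, free: EnzymeState, bound: EnzymeState) -> None:
        other = free.allo if site == "catalytic" else free.cat
        suffix = _binding_suffix(site, ligand, other)
        substrate = SUBSTRATE_ID[ligand]
        bindings.append(
            Reaction(
                id=f"bind_{suffix}",
                kind="binding",
                site=site,
                reactants=((free.species_id, 1), (substrate, 1)),
                products=((bound.species_id, 1),),
                rate_constant_ref=f"kf_{suffix}",
            )
        )
        unbindings.append(
            Reaction(
                id=f"unbind_{suffix}",
                kind="unbinding",
                site=site,
                reactants=((bound.species_id, 1),),
                products=((free.species_id, 1), (substrate, 1)),
                rate_constant_ref=f"kr_{suffix}",
            )
        )

    # Catalytic-site binding: any allosteric occupancy, catalytic site empty.
    for allo in OCCUPANCIES:
        for ligand in LIGANDS:
            add_pair(
                "catalytic",
                ligand,
                EnzymeState(SiteOccupancy.EMPTY, allo),
                EnzymeState(ligand, allo),
            )
    # Allosteric-site binding: any catalytic occupancy, allosteric site empty.
    for cat in OCCUPANCIES:
        for ligand in LIGANDS:
            add_pair(
                "allosteric",
                ligand,
                EnzymeState(cat, SiteOccupancy.EMPTY),
                EnzymeState(cat, ligand),
            )

    turnovers: list[Reaction] = []
    for cat in LIGANDS:
        for allo in OCCUPANCIES:
            state = EnzymeState(cat, allo)
            if state == DEAD_STATE:
                continue  # 2-AG in both sites: no turnover
            regenerated = EnzymeState(SiteOccupancy.EMPTY, allo)
            suffix = f"{cat.value}__allo_{allo.value}"
            turnovers.append(
                Reaction(
                    id=f"turnover_{suffix}",
                    kind="turnover",
                    site="none",
                    reactants=((state.species_id, 1),),
                    products=((regenerated.species_id, 1), (PRODUCT_ID[cat], 1)),
                    rate_constant_ref=f"kcat_{suffix}",
                )
            )

    return ReactionNetwork(tuple(species), tuple(bindings + unbindings + turnovers))


def rate_law(
    reaction: Reaction,
    concentrations: Mapping[str, float],
    params: Mapping[str, float],
) -> float:
    """Instantaneous mass-action rate of ``reaction`` in uM/s.

    Binding: ``kf * [enzyme state] * [substrate]``; unbinding and turnover:
    ``k * [complex]``.  Raises :class:`MissingParameterError` if the referenced
    rate constant is absent.
    """
    name = reaction.rate_constant_ref
    try:
        k = params[name]
    except KeyError as exc:
        raise MissingParameterError(name) from exc
    rate = float(k)
    for species_id, count in reaction.reactants:
        conc = concentrations[species_id]
        if conc < 0:
            raise ValueError(f"negative concentration for {species_id}: {conc}")
        rate *= conc**count
    return rate


def binding_cycles() -> list[dict]:
    """The four thermodynamic binding cycles of the network.

    For each ordered ligand pair (X into the catalytic site, Y into the
    allosteric site) the two binding orders form a closed cycle

        E -> E(cat=X) -> E(cat=X,allo=Y)   versus   E -> E(allo=Y) -> E(cat=X,allo=Y)

    Detailed balance requires the product of association equilibrium constants
    (kf/kr) along one order to equal the product along the other.  Each cycle
    is reported as ``numerator``/``denominator`` lists of (kf, kr) name pairs;
    closure means their K-products are equal.
    """
    cycles = []
    for x in LIGANDS:
        for y in LIGANDS:
            cat_first = _binding_suffix("catalytic", x, SiteOccupancy.EMPTY)
            then_allo = _binding_suffix("allosteric", y, x)
            allo_first = _binding_suffix("allosteric", y, SiteOccupancy.EMPTY)
            then_cat = _binding_suffix("catalytic", x, y)
            cycles.append(
                {
                    "cat_ligand": x.value,
                    "allo_ligand": y.value,
                    "numerator": [
                        (f"kf_{cat_first}", f"kr_{cat_first}"),
                        (f"kf_{then_allo}", f"kr_{then_allo}"),
                    ],
                    "denominator": [
                        (f"kf_{allo_first}", f"kr_{allo_first}"),
                        (f"kf_{then_cat}", f"kr_{then_cat}"),
                    ],
                }
            )
    return cycles


# ---------------------------------------------------------------------------
# JSON round-trip

def _species_to_dict(sp: Species) -> dict:
    d: dict = {"id": sp.id, "role": sp.role}
    if sp.state is not None:
        d["state"] = {"cat": sp.state.cat.value, "allo": sp.state.allo.value}
    return d


def _species_from_dict(d: dict) -> Species:
    state = None
    if "state" in d:
        state = EnzymeState(SiteOccupancy(d["state"]["cat"]), SiteOccupancy(d["state"]["allo"]))
    return Species(d["id"], d["role"], state)


def network_to_json(network: ReactionNetwork, indent: int | None = 2) -> str:
    """Serialize a network to JSON (losslessly round-trippable)."""
    payload = {
        "species": [_species_to_dict(sp) for sp in network.species],
        "reactions": [
            {
                "id": rx.id,
                "kind": rx.kind,
                "site": rx.site,
                "reactants": [list(pair) for pair in rx.reactants],
                "products": [list(pair) for pair in rx.products],
                "rate_constant_ref": rx.rate_constant_ref,
            }
            for rx in network.reactions
        ],
    }
    return json.dumps(payload, indent=indent)


def network_from_json(text: str) -> ReactionNetwork:
    payload = json.loads(text)
    species = tuple(_species_from_dict(d) for d in payload["species"])
    reactions = tuple(
        Reaction(
            id=d["id"],
            kind=d["kind"],
            site=d["site"],
            reactants=tuple((s, int(n)) for s, n in d["reactants"]),
            products=tuple((s, int(n)) for s, n in d["products"]),
            rate_constant_ref=d["rate_constant_ref"],
        )
        for d in payload["reactions"]
    )
    return ReactionNetwork(species, reactions)
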