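"""Atom-transition metabolic networks.

A network is a set of reactions with per-carbon atom maps, plus metabolite
pool sizes (µmol g⁻¹ DW), net fluxes (µmol g⁻¹ DW s⁻¹), entry metabolites with
their medium ¹³C enrichment, and optional per-metabolite dilution fractions
(the share of a measured pool that never labels, e.g. a vacuolar or
non-photosynthetic subpool).

The system is metabolically stationary — pools and fluxes are constant and
every internal metabolite is flux-balanced — while the isotopic state evolves
after a step change of the input enrichment at t = 0.

Text format, one reaction per line::

    name: A + B -> C + D | ab + c : cab, d

Lower-case letters identify carbon atoms; the concatenated substrate strings
define them and the comma-separated product strings redistribute them.
``A + B <-> C | ...`` expands into ``name_f`` and ``name_b``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Reaction",
    "AtomNetwork",
    "NetworkError",
    "parse_reaction",
    "parse_network",
    "builtin_network",
]


class NetworkError(ValueError):
    """Malformed or unbalanced network definition."""


@dataclass(frozen=True)
class Reaction:
    """One reaction with its carbon atom map.

    ``substrates`` and ``products`` are tuples of ``(metabolite, atom_string)``;
    the multiset of letters on both sides must coincide exactly (each substrate
    carbon maps to exactly one product carbon).
    """

    name: str
    substrates: tuple
    products: tuple

    def __post_init__(self) -> None:
        sub_letters = "".join(a for _, a in self.substrates)
        prod_letters = "".join(a for _, a in self.products)
        if len(set(sub_letters)) != len(sub_letters):
            raise NetworkError(f"{self.name}: duplicate substrate atom letters")
        if sorted(sub_letters) != sorted(prod_letters):
            raise NetworkError(
                f"{self.name}: substrate atoms {sub_letters!r} do not balance "
                f"product atoms {prod_letters!r}"
            )

    def atom_origin(self, product_index: int) -> list:
        """For each atom of product ``product_index``: (substrate_index, position)."""
        lookup = {}
        for si, (_, atoms) in enumerate(self.substrates):
            for pos, letter in enumerate(atoms):
                lookup[letter] = (si, pos)
        _, patoms = self.products[product_index]
        return [lookup[letter] for letter in patoms]


_RX_LINE = re.compile(
    r"^\s*(?P<name>[\w.-]+)\s*:\s*(?P<stoich>.+?)\s*\|\s*(?P<atoms>.+?)\s*$"
)


def parse_reaction(line: str) -> list[Reaction]:
    """Parse one reaction line, expanding ``<->`` into forward/backward pairs."""
    m = _RX_LINE.match(line)
    if not m:
        raise NetworkError(f"cannot parse reaction line: {line!r}")
    name, stoich, atoms = m.group("name", "stoich", "atoms")
    reversible = "<->" in stoich
    lhs, rhs = re.split(r"<->|->", stoich)
    sub_mets = [s.strip() for s in lhs.split("+")]
    prod_mets = [s.strip() for s in rhs.split("+")]
    try:
        sub_atoms_part, prod_atoms_part = atoms.split(":")
    except ValueError as exc:
        raise NetworkError(f"{name}: atom map needs one ':' separator") from exc
    sub_atoms = [s.strip() for s in sub_atoms_part.split("+")]
    prod_atoms = [s.strip() for s in prod_atoms_part.split(",")]
    if len(sub_atoms) != len(sub_mets) or len(prod_atoms) != len(prod_mets):
        raise NetworkError(f"{name}: atom map does not match stoichiometry")
    substrates = tuple(zip(sub_mets, sub_atoms))
    products = tuple(zip(prod_mets, prod_atoms))
    if not reversible:
        return [Reaction(name, substrates, products)]
    return [
        Reaction(f"{name}_f", substrates, products),
        Reaction(f"{name}_b", products, substrates),
    ]


def parse_network(
    text: str,
    pools: dict,
    fluxes: dict,
    inputs: dict,
    dilutions: dict | None = None,
) -> "AtomNetwork":
    """Parse a multi-line reaction block and assemble a validated network."""
    reactions = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            reactions.extend(parse_reaction(line))
    return AtomNetwork(reactions, dict(pools), dict(fluxes), dict(inputs),
                       dict(dilutions or {}))


@dataclass
class AtomNetwork:
    """A validated, flux-balanced atom-transition network."""

    reactions: list
    pools: dict
    fluxes: dict
    inputs: dict
    dilutions: dict = field(default_factory=dict)

    _BALANCE_TOL = 1e-9

    def __post_init__(self) -> None:
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate reaction names")
        missing = [n for n in names if n not in self.fluxes]
        if missing:
            raise NetworkError(f"no flux value for reactions: {missing}")
        for n, v in self.fluxes.items():
            if v < 0:
                raise NetworkError(f"negative net flux for {n}")
        for met, p in self.pools.items():
            if p <= 0:
                raise NetworkError(f"non-positive pool size for {met}")
        for met, d in self.dilutions.items():
            if not 0.0 <= d <= 1.0:
                raise NetworkError(f"dilution for {met} outside [0, 1]")
        self._carbon_counts()  # consistency check
        self.check_steady_state()

    # -- structure ---------------------------------------------------------

    def _carbon_counts(self) -> dict:
        counts: dict = {}
        for rxn in self.reactions:
            for met, atoms in list(rxn.substrates) + list(rxn.products):
                if met in counts and counts[met] != len(atoms):
                    raise NetworkError(
                        f"{met}: inconsistent carbon count "
                        f"({counts[met]} vs {len(atoms)} in {rxn.name})"
                    )
                counts.setdefault(met, len(atoms))
        return counts

    @property
    def carbon_counts(self) -> dict:
        return self._carbon_counts()

    @property
    def internal_metabolites(self) -> list:
        return list(self.pools)

    def n_carbons(self, met: str) -> int:
        return self._carbon_counts()[met]

    def stoichiometric_matrix(self):
        """(S, metabolites, reaction_names): S[i, j] = net production of met i by rxn j."""
        mets = self.internal_metabolites
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, _ in rxn.substrates:
                if met in idx:
                    S[idx[met], j] -= 1
            for met, _ in rxn.products:
                if met in idx:
                    S[idx[met], j] += 1
        return S, mets, [r.name for r in self.reactions]

    def flux_vector(self) -> np.ndarray:
        return np.array([self.fluxes[r.name] for r in self.reactions])

    def check_steady_state(self) -> None:
        """Every internal metabolite must be produced and consumed at equal rates."""
        S, mets, _ = self.stoichiometric_matrix()
        v = self.flux_vector()
        resid = S @ v
        scale = max(1.0, float(np.abs(v).max()))
        bad = [m for m, r in zip(mets, resid) if abs(r) > self._BALANCE_TOL * scale]
        if bad:
            raise NetworkError(f"steady-state mass balance violated for: {bad}")

    def turnover(self, met: str) -> float:
        """Total consumption flux of ``met`` divided by its pool size (s⁻¹)."""
        out = 0.0
        for rxn in self.reactions:
            for m, _ in rxn.substrates:
                if m == met:
                    out += self.fluxes[rxn.name]
        return out / self.pools[met]

    def total_input_carbon_flux(self) -> float:
        """Gross carbon uptake through entry metabolites (µmol C g⁻¹ DW s⁻¹)."""
        total = 0.0
        for rxn in self.reactions:
            for met, atoms in rxn.substrates:
                if met in self.inputs:
                    total += self.fluxes[rxn.name] * len(atoms)
        return total

    def with_parameters(self, fluxes=None, pools=None, dilutions=None) -> "AtomNetwork":
        """Copy of the network with some parameters replaced (revalidated)."""
        return AtomNetwork(
            self.reactions,
            dict(pools if pools is not None else self.pools),
            dict(fluxes if fluxes is not None else self.fluxes),
            dict(self.inputs),
            dict(dilutions if dilutions is not None else self.dilutions),
        )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_MINIMAL_CHAIN_TEXT = """
asm: CO2 + CO2 + CO2 -> A | a + b + c : abc
ab:  A -> B | abc : abc
bx:  B -> BSINK | abc : abc
"""

# Toy Calvin-Benson cycle: carboxylation, triose/pentose rearrangement with the
# cleavage/condensation steps that make atom bookkeeping non-trivial, starch and
# sucrose export, lower glycolysis to PEP and anaplerotic carboxylation to
# malate.  Small enough (10 internal metabolites, <= 7 carbons) for exhaustive
# isotopomer simulation.
_CBC_TOY_TEXT = """
rbc:    RuBP + CO2 -> PGA + PGA    | abcde + f : fba, cde
pgk:    PGA -> TP                  | abc : abc
ald:    TP + TP -> FBP             | abc + def : abcdef
fbp:    FBP -> F6P                 | abcdef : abcdef
tk1:    F6P + TP -> RuBP + E4P     | abcdef + ghi : abghi, cdef
ald2:   E4P + TP -> S7P            | abcd + efg : efgabcd
tk2:    S7P + TP -> RuBP + RuBP    | abcdefg + hij : abhij, cdefg
pgi:    F6P -> G6P                 | abcdef : abcdef
sts:    G6P -> STARCH              | abcdef : abcdef
sps:    F6P -> SUCROSE             | abcdef : abcdef
eno:    PGA -> PEP                 | abc : abc
pk:     PEP -> PYRSINK             | abc : abc
pepc:   PEP + CO2 -> MAL           | abc + d : abcd
mex:    MAL -> MALSINK             | abcd : abcd
"""

_CBC_TOY_FLUXES = {
    "rbc": 0.30, "pgk": 0.56, "ald": 0.13, "fbp": 0.13,
    "tk1": 0.10, "ald2": 0.10, "tk2": 0.10,
    "pgi": 0.02, "sts": 0.02, "sps": 0.01,
    "eno": 0.04, "pk": 0.025, "pepc": 0.015, "mex": 0.015,
}
_CBC_TOY_POOLS = {
    "RuBP": 0.35, "PGA": 1.1, "TP": 0.16, "FBP": 0.21, "F6P": 0.8,
    "E4P": 0.06, "S7P": 0.37, "G6P": 1.4, "PEP": 0.28, "MAL": 6.0,
}

# Fuller variant: photorespiration (2PG -> glycine / recycling), explicit
# pentose phosphates, TCA entry via PEPC and pyruvate dehydrogenase, amino acid
# sinks.  Still exhaustively simulable (~700 isotopomer states).
_CBC_FULL_TEXT = """
rbc_c:  RuBP + CO2 -> PGA + PGA    | abcde + f : fba, cde
rbc_o:  RuBP -> PGA + PGO          | abcde : cde, ba
gox:    PGO + PGO -> PGA + CO2X    | ab + cd : bcd, a
glys:   PGO -> GLY                 | ab : ab
glyx:   GLY -> GLYSINK             | ab : ab
pgk:    PGA -> TP                  | abc : abc
ald:    TP + TP -> FBP             | abc + def : abcdef
fbp:    FBP -> F6P                 | abcdef : abcdef
tk1:    F6P + TP -> X5P + E4P      | abcdef + ghi : abghi, cdef
ald2:   E4P + TP -> S7P            | abcd + efg : efgabcd
tk2:    S7P + TP -> R5P + X5P      | abcdefg + hij : cdefg, abhij
rpi:    R5P -> RU5P                | abcde : abcde
rpe:    X5P -> RU5P                | abcde : abcde
prk:    RU5P -> RuBP               | abcde : abcde
pgi:    F6P -> G6P                 | abcdef : abcdef
sts:    G6P -> STARCH              | abcdef : abcdef
sps:    F6P + G6P -> SUCROSE       | abcdef + ghijkl : abcdefghijkl
eno:    PGA -> PEP                 | abc : abc
pk:     PEP -> PYR                 | abc : abc
pyrx:   PYR -> PYRSINK             | abc : abc
pepc:   PEP + CO2 -> OAA           | abc + d : abcd
pdh:    PYR -> ACA + CO2X          | abc : bc, a
cs:     OAA + ACA -> CIT           | abcd + ef : abcdef
idh:    CIT -> GLU + CO2X          | abcdef : abcde, f
pro:    GLU -> PRO                 | abcde : abcde
prox:   PRO -> PROSINK             | abcde : abcde
glux:   GLU -> GLUSINK             | abcde : abcde
aat:    OAA -> ASP                 | abcd : abcd
aspx:   ASP -> ASPSINK             | abcd : abcd
mdh:    OAA -> MAL                 | abcd : abcd
malx:   MAL -> MALSINK             | abcd : abcd
"""

_CBC_FULL_FLUXES = {
    "rbc_c": 0.24, "rbc_o": 0.06, "gox": 0.025, "glys": 0.01, "glyx": 0.01,
    "pgk": 0.54, "ald": 0.12, "fbp": 0.12,
    "tk1": 0.10, "ald2": 0.10, "tk2": 0.10,
    "rpi": 0.10, "rpe": 0.20, "prk": 0.30,
    "pgi": 0.014, "sts": 0.008, "sps": 0.006,
    "eno": 0.025, "pk": 0.015, "pyrx": 0.009,
    "pepc": 0.010, "pdh": 0.006, "cs": 0.006, "idh": 0.006,
    "pro": 0.002, "prox": 0.002, "glux": 0.004,
    "aat": 0.002, "aspx": 0.002, "mdh": 0.002, "malx": 0.002,
}
_CBC_FULL_POOLS = {
    "RuBP": 0.35, "PGA": 1.1, "PGO": 0.08, "TP": 0.16, "FBP": 0.21,
    "F6P": 0.8, "E4P": 0.06, "S7P": 0.37, "R5P": 0.09, "X5P": 0.12,
    "RU5P": 0.10, "G6P": 1.4, "PEP": 0.28, "PYR": 0.5, "ACA": 0.05,
    "OAA": 0.10, "CIT": 3.0, "GLU": 12.0, "ASP": 4.0, "MAL": 6.0,
    "GLY": 1.5, "PRO": 2.5,
}

#: Default medium ¹³C enrichment of the inorganic-carbon input (the labelling
#: experiments reached only ~50% ¹³C in the medium).
DEFAULT_MEDIUM_ENRICHMENT = 0.5


def builtin_network(preset: str, medium_enrichment: float = DEFAULT_MEDIUM_ENRICHMENT,
                    dilutions: dict | None = None) -> AtomNetwork:
    """Return a balanced preset network.

    Presets
    -------
    ``minimal_chain``
        CO₂ → A(3C) → B(3C) → sink, single flux; closed-form checkable.
    ``cbc_toy``
        10-metabolite Calvin–Benson cycle with starch/sucrose export, lower
        glycolysis and PEPC anaplerosis; tractable by brute-force isotopomer
        simulation.
    ``cbc_full``
        22-metabolite variant adding photorespiration, explicit pentose
        phosphates and TCA-derived amino acids.
    """
    inputs = {"CO2": medium_enrichment}
    if preset == "minimal_chain":
        return parse_network(
            _MINIMAL_CHAIN_TEXT,
            pools={"A": 1.0, "B": 2.0},
            fluxes={"asm": 0.1, "ab": 0.1, "bx": 0.1},
            inputs=inputs,
            dilutions=dilutions,
        )
    if preset == "cbc_toy":
        return parse_network(
            _CBC_TOY_TEXT, pools=_CBC_TOY_POOLS, fluxes=_CBC_TOY_FLUXES,
            inputs=inputs, dilutions=dilutions,
        )
    if preset == "cbc_full":
        return parse_network(
            _CBC_FULL_TEXT, pools=_CBC_FULL_POOLS, fluxes=_CBC_FULL_FLUXES,
            inputs=inputs, dilutions=dilutions,
        )
    raise NetworkError(f"unknown preset {preset!r}")
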