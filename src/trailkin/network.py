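"""Generic mass-action reaction-network engine.

Every biochemical step of the apoptosis cascade is one of four reaction
paradigms:

1. **Catalysis, enzyme recycled** — ``E + S <=> E:S -> E + P`` with forward
   rate ``k_plus [E][S]``, reverse rate ``k_minus [E:S]`` and catalytic rate
   ``k_cat [E:S]``.
2. **Bind-and-convert** — ``E + S <=> E:S -> P``: the complex itself turns
   into the product, consuming both partners (receptor activation and pore
   formation use this form).  As printed in its source the product line of
   this paradigm does not conserve mass; it is implemented here with
   ``d[P]/dt = +k_cat [E:S]`` so that both the E- and the S-moiety are
   conserved, which is the only mass-consistent reading.
3. **Reversible binding** — ``E + S <=> E:S`` with no product.  ``E`` and
   ``S`` may name the same species (homodimerization); the forward rate is
   then ``k_plus [E]^2`` and two copies are consumed per event.
4. **Translocation** — first-order reversible transport of one species
   between compartments, ``X_src <=> X_dst`` at rates ``k_plus``/``k_minus``.

Networks are static descriptions (:class:`NetworkModel`); the engine derives
a vectorized ODE right-hand side, its analytic Jacobian, and the conserved
moieties (a basis of the left null space of the stoichiometry matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import sympy

__all__ = [
    "NetworkValidationError",
    "SpeciesDef",
    "ReactionDef",
    "NetworkModel",
    "build_network",
    "rate_function",
    "jacobian_function",
    "conserved_moieties",
    "read_network_tsv",
    "write_network_tsv",
]

COMPARTMENTS = ("surface", "cytosol", "mitochondria")
ROLES = ("ligand", "receptor", "intracellular")


class NetworkValidationError(ValueError):
    """A network description violates its structural contract."""


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species: a name, a compartment, an initial amount.

    Intracellular species are carried as molecules per cell; the
    ligand/receptor surface species follow the units convention of the
    scenario that configures them (see :mod:`trailkin.apoptosis`).
    """

    name: str
    compartment: str = "cytosol"
    initial: float = 0.0
    role: str = "intracellular"

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkValidationError("species name must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"unknown compartment {self.compartment!r} for species {self.name!r}")
        if self.role not in ROLES:
            raise NetworkValidationError(f"unknown role {self.role!r} for species {self.name!r}")
        if not (self.initial >= 0) or not math.isfinite(self.initial):
            raise NetworkValidationError(
                f"initial amount of {self.name!r} must be finite and >= 0")


@dataclass(frozen=True)
class ReactionDef:
    """One reaction in paradigm form.

    Field usage by paradigm:

    ========  =======  =========  =======  =======
    paradigm  enzyme   substrate  complex  product
    ========  =======  =========  =======  =======
    1         E        S          E:S      P
    2         E        S          E:S      P
    3         E        S          E:S      --
    4         --       source     --       destination
    ========  =======  =========  =======  =======
    """

    label: str
    paradigm: int
    enzyme: Optional[str] = None
    substrate: Optional[str] = None
    complex: Optional[str] = None
    product: Optional[str] = None
    k_plus: float = 0.0
    k_minus: float = 0.0
    k_cat: float = 0.0

    def __post_init__(self) -> None:
        if self.paradigm not in (1, 2, 3, 4):
            raise NetworkValidationError(f"{self.label}: unknown paradigm {self.paradigm!r}")
        for rname in ("k_plus", "k_minus", "k_cat"):
            v = getattr(self, rname)
            if not (v >= 0) or not math.isfinite(v):
                raise NetworkValidationError(f"{self.label}: {rname} must be finite and >= 0")
        if self.paradigm in (1, 2):
            missing = [f for f in ("enzyme", "substrate", "complex", "product")
                       if getattr(self, f) is None]
        elif self.paradigm == 3:
            missing = [f for f in ("enzyme", "substrate", "complex") if getattr(self, f) is None]
            if self.product is not None:
                raise NetworkValidationError(
                    f"{self.label}: paradigm 3 (pure binding) admits no product")
            if self.k_cat != 0.0:
                raise NetworkValidationError(
                    f"{self.label}: paradigm 3 (pure binding) admits no catalytic rate")
        else:  # paradigm 4
            missing = [f for f in ("substrate", "product") if getattr(self, f) is None]
        if missing:
            raise NetworkValidationError(f"{self.label}: paradigm {self.paradigm} "
                                         f"requires fields {missing}")

    @property
    def species_refs(self) -> tuple[str, ...]:
        return tuple(s for s in (self.enzyme, self.substrate, self.complex, self.product)
                     if s is not None)


# One elementary unidirectional flux: rate = k * y[i] (* y[j] if j >= 0),
# applied to the state through one stoichiometry column.
@dataclass(frozen=True)
class _Term:
    k: float
    i: int
    j: int  # -1 for unimolecular


@dataclass(frozen=True, eq=False)
class NetworkModel:
    """Validated static description of a mass-action network."""

    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    stoichiometry: np.ndarray = field(repr=False)   # (n_species, n_terms)
    _terms: tuple[_Term, ...] = field(repr=False)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no species named {name!r}") from None

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    def with_overrides(
        self,
        initials: Optional[dict[str, float]] = None,
        reaction_rates: Optional[dict[str, dict[str, float]]] = None,
    ) -> "NetworkModel":
        """Return a copy with some initial amounts and/or reaction rate
        constants replaced; everything else (including ordering) is kept."""
        initials = dict(initials or {})
        reaction_rates = {k: dict(v) for k, v in (reaction_rates or {}).items()}
        species = []
        for s in self.species:
            if s.name in initials:
                species.append(replace(s, initial=initials.pop(s.name)))
            else:
                species.append(s)
        if initials:
            raise KeyError(f"unknown species in initial overrides: {sorted(initials)}")
        reactions = []
        for r in self.reactions:
            if r.label in reaction_rates:
                reactions.append(replace(r, **reaction_rates.pop(r.label)))
            else:
                reactions.append(r)
        if reaction_rates:
            raise KeyError(f"unknown reactions in rate overrides: {sorted(reaction_rates)}")
        return build_network(species, reactions)


def _expand_terms(
    reactions: Sequence[ReactionDef], index: dict[str, int]
) -> tuple[list[_Term], np.ndarray]:
    cols: list[np.ndarray] = []
    terms: list[_Term] = []
    n = len(index)

    def col(changes: dict[str, float]) -> np.ndarray:
        c = np.zeros(n)
        for name, dv in changes.items():
            c[index[name]] += dv
        return c

    for r in reactions:
        if r.paradigm == 4:
            terms.append(_Term(r.k_plus, index[r.substrate], -1))
            cols.append(col({r.substrate: -1, r.product: +1}))
            terms.append(_Term(r.k_minus, index[r.product], -1))
            cols.append(col({r.substrate: +1, r.product: -1}))
            continue
        E, S, ES = r.enzyme, r.substrate, r.complex
        # forward binding (homodimerization consumes two copies of E == S)
        if E == S:
            terms.append(_Term(r.k_plus, index[E], index[E]))
            cols.append(col({E: -2, ES: +1}))
            terms.append(_Term(r.k_minus, index[ES], -1))
            cols.append(col({E: +2, ES: -1}))
        else:
            terms.append(_Term(r.k_plus, index[E], index[S]))
            cols.append(col({E: -1, S: -1, ES: +1}))
            terms.append(_Term(r.k_minus, index[ES], -1))
            cols.append(col({E: +1, S: +1, ES: -1}))
        if r.paradigm == 1:
            terms.append(_Term(r.k_cat, index[ES], -1))
            cols.append(col({ES: -1, E: +1, r.product: +1}))
        elif r.paradigm == 2:
            terms.append(_Term(r.k_cat, index[ES], -1))
            cols.append(col({ES: -1, r.product: +1}))
    if cols:
        stoich = np.column_stack(cols)
    else:
        stoich = np.zeros((n, 0))
    return terms, stoich


def build_network(
    species: Iterable[SpeciesDef], reactions: Iterable[ReactionDef]
) -> NetworkModel:
    """Validate a species/reaction description and assemble its
    stoichiometry matrix.

    Raises :class:`NetworkValidationError` on duplicate species names,
    dangling references, duplicate reaction labels, or malformed reactions.
    """
    species = tuple(species)
    reactions = tuple(reactions)
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise NetworkValidationError(f"duplicate species names: {dupes}")
    labels = [r.label for r in reactions]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NetworkValidationError(f"duplicate reaction labels: {dupes}")
    index = {n: i for i, n in enumerate(names)}
    for r in reactions:
        for ref in r.species_refs:
            if ref not in index:
                raise NetworkValidationError(
                    f"{r.label}: reference to undeclared species {ref!r}")
    terms, stoich = _expand_terms(reactions, index)
    return NetworkModel(species=species, reactions=reactions,
                        stoichiometry=stoich, _terms=tuple(terms))


def rate_function(model: NetworkModel) -> Callable[[float, np.ndarray], np.ndarray]:
    """Derivative evaluator ``f(t, y) -> dy/dt`` for the network ODE.

    Contributions from all reactions sum; the evaluator rejects state
    vectors of the wrong length.
    """
    n = model.n_species
    k = np.array([t.k for t in model._terms])
    i1 = np.array([t.i for t in model._terms], dtype=int)
    i2 = np.array([t.j for t in model._terms], dtype=int)
    bimol = i2 >= 0
    i2c = np.where(bimol, i2, 0)
    N = model.stoichiometry

    def f(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (n,):
            raise ValueError(f"state vector has shape {y.shape}, expected ({n},)")
        v = k * y[i1]
        v[bimol] *= y[i2c[bimol]]
        return N @ v

    return f


def jacobian_function(model: NetworkModel) -> Callable[[float, np.ndarray], np.ndarray]:
    """Analytic Jacobian ``J(t, y)`` of the mass-action right-hand side."""
    n = model.n_species
    m = len(model._terms)
    k = np.array([t.k for t in model._terms])
    i1 = np.array([t.i for t in model._terms], dtype=int)
    i2 = np.array([t.j for t in model._terms], dtype=int)
    bimol = i2 >= 0
    i2c = np.where(bimol, i2, 0)
    N = model.stoichiometry
    rows = np.arange(m)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        dv = np.zeros((m, n))
        # d(k y_i y_j)/d y_i = k y_j ; unimolecular terms have y_j == 1
        w = np.ones(m)
        w[bimol] = y[i2c[bimol]]
        dv[rows, i1] += k * w
        dv[rows[bimol], i2[bimol]] += k[bimol] * y[i1[bimol]]
        return N @ dv

    return jac


def conserved_moieties(model: NetworkModel) -> list[np.ndarray]:
    """Basis of conserved linear combinations of species amounts.

    Returns integer vectors ``c`` with ``c . dy/dt = 0`` identically — the
    left null space of the stoichiometry matrix, computed exactly over the
    rationals and scaled to smallest integers.  Species that take part in no
    reaction contribute their own unit vector.
    """
    N = sympy.Matrix(model.stoichiometry.astype(int))
    basis = N.T.nullspace()
    out = []
    for v in basis:
        denoms = [sympy.fraction(x)[1] for x in v]
        scale = sympy.lcm(denoms) if denoms else 1
        vi = (v * scale).applyfunc(sympy.nsimplify)
        arr = np.array([int(x) for x in vi], dtype=int)
        if (arr <= 0).all():
            arr = -arr
        out.append(arr)
    return out


# ---------------------------------------------------------------------------
# flat-text fixture format: a [species] table and a [reactions] table
# ---------------------------------------------------------------------------

_SPECIES_COLS = ("name", "compartment", "role", "initial")
_REACTION_COLS = ("label", "paradigm", "enzyme", "substrate", "complex",
                  "product", "k_plus", "k_minus", "k_cat")


def write_network_tsv(model: NetworkModel, path, header_comment: str = "") -> None:
    """Serialize a network as a two-table tab-separated text file.

    The writer is deterministic: rebuilding the same model yields a
    byte-identical file.
    """
    lines = []
    for c in header_comment.splitlines():
        lines.append(f"# {c}".rstrip())
    lines.append("[species]")
    lines.append("\t".join(_SPECIES_COLS))
    for s in model.species:
        lines.append("\t".join([s.name, s.compartment, s.role, repr(float(s.initial))]))
    lines.append("[reactions]")
    lines.append("\t".join(_REACTION_COLS))
    for r in model.reactions:
        row = [r.label, str(r.paradigm)]
        row += [x if x is not None else "-" for x in
                (r.enzyme, r.substrate, r.complex, r.product)]
        row += [repr(float(r.k_plus)), repr(float(r.k_minus)), repr(float(r.k_cat))]
        lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_network_tsv(path) -> NetworkModel:
    """Parse a network fixture written by :func:`write_network_tsv`."""
    species: list[SpeciesDef] = []
    reactions: list[ReactionDef] = []
    section = None
    header: Optional[list[str]] = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.strip() in ("[species]", "[reactions]"):
                section = line.strip()[1:-1]
                header = None
                continue
            if section is None:
                raise NetworkValidationError(f"{path}:{lineno}: content before any section")
            cells = line.split("\t")
            if header is None:
                header = cells
                expect = _SPECIES_COLS if section == "species" else _REACTION_COLS
                if tuple(header) != expect:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: bad {section} header {header}")
                continue
            row = dict(zip(header, cells))
            try:
                if section == "species":
                    species.append(SpeciesDef(
                        name=row["name"], compartment=row["compartment"],
                        role=row["role"], initial=float(row["initial"])))
                else:
                    opt = {f: (None if row[f] == "-" else row[f])
                           for f in ("enzyme", "substrate", "complex", "product")}
                    reactions.append(ReactionDef(
                        label=row["label"], paradigm=int(row["paradigm"]),
                        k_plus=float(row["k_plus"]), k_minus=float(row["k_minus"]),
                        k_cat=float(row["k_cat"]), **opt))
            except (KeyError, ValueError) as exc:
                if isinstance(exc, NetworkValidationError):
                    raise
                raise NetworkValidationError(f"{path}:{lineno}: {exc}") from exc
    return build_network(species, reactions)
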