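"""Core reaction-network data model.

Species, reactions, rate laws and parameter sets for the BMEC signaling
network.  A :class:`ModelNetwork` is a plain container; the numerical
right-hand side is compiled from it by :mod:`bmecsim.rhs`.

Unit conventions
----------------
* proteins / complexes: relative copy-number units (quiescent totals are
  normalized so the dominant pool is 1.0 where literature copy numbers are
  unavailable);
* metabolites and free radicals: relative units with quiescent value 1;
* O2: dissolved fraction (0.21 under control);
* glucose: mmol/L (5.05 under control);
* ligands: molecules per cell (see :func:`bmecsim.protocols.convert_dose`);
* time: hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

COMPARTMENTS = {
    "cytosol",
    "nucleus",
    "ER",
    "mitochondrion",
    "membrane",
    "medium",
    "environment",
}

ROLE_TAGS = {
    "ligand",
    "receptor",
    "kinase",
    "transcription_factor",
    "metabolite",
    "radical",
    "marker",
    "environment",
}

RATE_LAW_KINDS = {
    "mass_action",
    "hill_activation",
    "hill_inhibition",
    "michaelis_menten",
    "zeroth_order_synthesis",
    "first_order_decay",
}

MODULES = {
    "inflammation",
    "survival",
    "hypoxia",
    "metabolism",
    "oxidative_stress",
    "environment",
}

#: the 12 functional markers of the phenotype grid, in display order
MARKERS = [
    "IL6",
    "IL1b",
    "CCL2",
    "Ang2",
    "SEMA3G",
    "BDNF",
    "ZO1",
    "Claudin5",
    "ROS",
    "ONOO",
    "p53",
    "Casp3",
]

#: markers treated as cumulatively secreted cytokines/chemokines
SECRETED_MARKERS = ["IL6", "IL1b", "CCL2"]

#: accepted aliases for species ids on input (the literature uses both
#: VEGFR Y1175 and Y1173 for the same PLCgamma-coupled site)
SPECIES_ALIASES = {
    "VEGFR_pY1173": "VEGFR_pY1175",
    "IkB": "IkBa",
}


class ConfigurationError(ValueError):
    """Raised for inconsistent network/parameter configurations."""


class SimulationError(RuntimeError):
    """Raised when numerical integration fails."""


@dataclass
class SpeciesDef:
    id: str
    compartment: str = "cytosol"
    initial_amount: float = 1.0
    role_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(
                f"unknown compartment {self.compartment!r} for species {self.id}"
            )
        if self.initial_amount < 0:
            raise ConfigurationError(f"negative initial amount for {self.id}")
        self.role_tags = frozenset(self.role_tags)
        bad = self.role_tags - ROLE_TAGS
        if bad:
            raise ConfigurationError(f"unknown role tags {bad} for {self.id}")


@dataclass
class RateLaw:
    """A reaction's kinetic form.

    ``rate_constant`` is resolved through the reaction's ``parameter_id`` in
    the active :class:`ParameterSet`; ``hill_K``/``hill_n`` apply to the
    reaction's primary regulator for the hill kinds, or to the substrate for
    ``michaelis_menten``.
    """

    kind: str = "mass_action"
    hill_K: float | None = None
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise ConfigurationError(f"unknown rate law kind {self.kind!r}")
        if self.kind in ("hill_activation", "hill_inhibition", "michaelis_menten"):
            if self.hill_K is None or self.hill_K <= 0:
                raise ConfigurationError(f"{self.kind} requires positive hill_K")
            if self.hill_n < 1:
                raise ConfigurationError("hill_n must be >= 1")


@dataclass
class Regulator:
    """A multiplicative modifier of a reaction flux.

    mode 'linear'   -> factor = [S]
    mode 'activate' -> factor = [S]^n / (K^n + [S]^n)
    mode 'inhibit'  -> factor = K^n / (K^n + [S]^n)
    """

    species: str
    mode: str
    K: float | None = None
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "activate", "inhibit"):
            raise ConfigurationError(f"unknown regulator mode {self.mode!r}")
        if self.mode != "linear" and (self.K is None or self.K <= 0):
            raise ConfigurationError(
                f"regulator on {self.species} ({self.mode}) needs positive K"
            )


@dataclass
class Reaction:
    id: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    regulators: list[Regulator] = field(default_factory=list)
    rate_law: RateLaw = field(default_factory=RateLaw)
    parameter_id: str = ""
    module: str = "environment"

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ConfigurationError(f"reaction {self.id}: no reactants or products")
        if self.module not in MODULES:
            raise ConfigurationError(
                f"reaction {self.id}: unknown module {self.module!r}"
            )
        for _, st in list(self.reactants) + list(self.products):
            if st < 1 or int(st) != st:
                raise ConfigurationError(
                    f"reaction {self.id}: stoichiometry must be integer >= 1"
                )

    @property
    def modifiers(self) -> list[str]:
        return [r.species for r in self.regulators]

    @property
    def parameter_ids(self) -> list[str]:
        return [self.parameter_id]


@dataclass
class ParameterSet:
    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"parameter {pid} must be positive, got {v}")
        for pid, (lo, hi) in self.bounds.items():
            v = self.values.get(pid)
            if v is None:
                raise ConfigurationError(f"bounds given for unknown parameter {pid}")
            if not (0 < lo <= v <= hi):
                raise ConfigurationError(
                    f"parameter {pid}={v} outside bounds ({lo}, {hi})"
                )

    @classmethod
    def with_default_bounds(cls, values: dict[str, float]) -> "ParameterSet":
        """Bounds at 0.5x-2x of the baseline value for every parameter."""
        bounds = {k: (0.5 * v, 2.0 * v) for k, v in values.items()}
        return cls(dict(values), bounds)

    def scaled(self, multipliers: dict[str, float]) -> "ParameterSet":
        """Return a copy with named parameters multiplied.

        Scaled copies represent perturbed cells / sensitivity samples; the
        original bounds are dropped (multipliers may compose outside them).
        """
        vals = dict(self.values)
        for pid, m in multipliers.items():
            if pid not in vals:
                raise ConfigurationError(f"unknown parameter {pid} in multipliers")
            if m <= 0:
                raise ConfigurationError(f"multiplier for {pid} must be positive")
            vals[pid] = vals[pid] * m
        return ParameterSet(vals)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.bounds))


@dataclass
class ModelNetwork:
    species: list[SpeciesDef]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = {i for i in ids if ids.count(i) > 1}
            raise ConfigurationError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = {i for i in rids if rids.count(i) > 1}
            raise ConfigurationError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            for sp, _ in list(r.reactants) + list(r.products):
                if sp not in known:
                    raise ConfigurationError(
                        f"reaction {r.id} references unknown species {sp}"
                    )
            for reg in r.regulators:
                if reg.species not in known:
                    raise ConfigurationError(
                        f"reaction {r.id} regulator references unknown species "
                        f"{reg.species}"
                    )

    # -- lookups ---------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, sid: str) -> int:
        sid = SPECIES_ALIASES.get(sid, sid)
        try:
            return self.species_ids.index(sid)
        except ValueError:
            raise KeyError(f"unknown species {sid!r}") from None

    def get_species(self, sid: str) -> SpeciesDef:
        return self.species[self.species_index(sid)]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    @property
    def module_labels(self) -> dict[str, str]:
        return {r.id: r.module for r in self.reactions}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def environment_indices(self) -> list[int]:
        return [
            i for i, s in enumerate(self.species) if "environment" in s.role_tags
        ]

    # -- structure -------------------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        """Dense species x reactions matrix of integer net stoichiometries."""
        n_sp, n_rx = len(self.species), len(self.reactions)
        idx = {s.id: i for i, s in enumerate(self.species)}
        mat = np.zeros((n_sp, n_rx))
        for j, r in enumerate(self.reactions):
            for sp, st in r.reactants:
                mat[idx[sp], j] -= st
            for sp, st in r.products:
                mat[idx[sp], j] += st
        return mat

    def validate(self) -> None:
        """Check the structural invariants beyond construction-time checks."""
        participating: set[str] = set()
        for r in self.reactions:
            participating.update(sp for sp, _ in r.reactants)
            participating.update(sp for sp, _ in r.products)
            participating.update(r.modifiers)
        orphans = set(self.species_ids) - participating
        if orphans:
            raise ConfigurationError(
                f"species not participating in any reaction: {sorted(orphans)}"
            )
        mat = self.stoichiometry_matrix()
        if mat.shape != (len(self.species), len(self.reactions)):
            raise ConfigurationError("inconsistent stoichiometry matrix shape")
        if not np.all(mat == np.round(mat)):
            raise ConfigurationError("non-integer stoichiometry matrix entries")

    def check_parameters(self, params: ParameterSet) -> None:
        missing = [
            r.parameter_id
            for r in self.reactions
            if r.parameter_id not in params.values
        ]
        if missing:
            raise ConfigurationError(
                f"unresolved parameter ids: {sorted(set(missing))}"
            )

    def influence_graph(self) -> nx.DiGraph:
        """Signed directed influence graph.

        Edge u -> v with sign +1 means u promotes accumulation of v
        (substrate/activator of a producing reaction, or inhibitor of a
        consuming one); sign -1 the converse.  Used to verify the causal
        wiring of the default model.
        """
        g = nx.DiGraph()
        for s in self.species:
            g.add_node(s.id)

        def add(u: str, v: str, sign: int) -> None:
            if u == v:
                return
            if g.has_edge(u, v):
                # keep first sign; parallel influences of mixed sign are rare
                return
            g.add_edge(u, v, sign=sign)

        for r in self.reactions:
            sources: list[tuple[str, int]] = []
            for sp, _ in r.reactants:
                sources.append((sp, +1))
            for reg in r.regulators:
                sources.append((reg.species, +1 if reg.mode != "inhibit" else -1))
            consumed = {sp for sp, _ in r.reactants}
            produced = {sp for sp, _ in r.products}
            for sp in produced - consumed:
                for u, sgn in sources:
                    add(u, sp, sgn)
            for sp in consumed - produced:
                for u, sgn in sources:
                    if u != sp:
                        add(u, sp, -sgn)
        return g
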