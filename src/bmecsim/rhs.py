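"""Compilation of a :class:`~bmecsim.network.ModelNetwork` into a fast ODE
right-hand side.

Every reaction flux has the form

    flux = k * prod(reactant^stoich) * prod(regulator factors)

with the base form determined by the rate-law kind (a ``michaelis_menten``
substrate contributes a saturating instead of a linear factor).  Factors are
evaluated in grouped numpy operations so one RHS call is a handful of
vectorized expressions regardless of network size.
"""

from __future__ import annotations

import numpy as np

from .network import ConfigurationError, ModelNetwork, ParameterSet


class CompiledRHS:
    """Callable ``(t, y) -> dy/dt`` plus per-reaction flux evaluation."""

    def __init__(
        self,
        network: ModelNetwork,
        params: ParameterSet,
        clamped: tuple[int, ...] | None = None,
    ) -> None:
        network.check_parameters(params)
        self.network = network
        self.n_species = len(network.species)
        self.n_reactions = len(network.reactions)
        sp_idx = {s.id: i for i, s in enumerate(network.species)}

        self.k = np.array(
            [params.values[r.parameter_id] for r in network.reactions], dtype=float
        )

        lin_rxn: list[int] = []  # linear factors: y[s]**p
        lin_sp: list[int] = []
        lin_pow: list[float] = []
        hill_rxn: list[int] = []  # hill factors: act or inh
        hill_sp: list[int] = []
        hill_K: list[float] = []
        hill_n: list[float] = []
        hill_inh: list[bool] = []

        for j, r in enumerate(network.reactions):
            kind = r.rate_law.kind
            # substrate factors
            if kind == "michaelis_menten":
                if len(r.reactants) != 1:
                    raise ConfigurationError(
                        f"reaction {r.id}: michaelis_menten needs one substrate"
                    )
                sp, st = r.reactants[0]
                if st != 1:
                    raise ConfigurationError(
                        f"reaction {r.id}: michaelis_menten substrate stoich must be 1"
                    )
                hill_rxn.append(j)
                hill_sp.append(sp_idx[sp])
                hill_K.append(r.rate_law.hill_K)
                hill_n.append(r.rate_law.hill_n)
                hill_inh.append(False)
            elif kind != "zeroth_order_synthesis":
                for sp, st in r.reactants:
                    lin_rxn.append(j)
                    lin_sp.append(sp_idx[sp])
                    lin_pow.append(float(st))
            # regulator factors; hill_activation / hill_inhibition take their
            # constants from the rate law for the primary (first) regulator
            for i, reg in enumerate(r.regulators):
                K, n, mode = reg.K, reg.n, reg.mode
                if i == 0 and kind in ("hill_activation", "hill_inhibition"):
                    K = r.rate_law.hill_K if K is None else K
                    n = r.rate_law.hill_n if reg.K is None else n
                    if mode == "linear":
                        mode = (
                            "activate" if kind == "hill_activation" else "inhibit"
                        )
                if mode == "linear":
                    lin_rxn.append(j)
                    lin_sp.append(sp_idx[reg.species])
                    lin_pow.append(1.0)
                else:
                    if K is None:
                        raise ConfigurationError(
                            f"reaction {r.id}: regulator {reg.species} missing K"
                        )
                    hill_rxn.append(j)
                    hill_sp.append(sp_idx[reg.species])
                    hill_K.append(K)
                    hill_n.append(n)
                    hill_inh.append(mode == "inhibit")

        self._lin_rxn = np.asarray(lin_rxn, dtype=np.intp)
        self._lin_sp = np.asarray(lin_sp, dtype=np.intp)
        self._lin_pow = np.asarray(lin_pow, dtype=float)
        self._lin_simple = bool(np.all(self._lin_pow == 1.0))
        self._hill_rxn = np.asarray(hill_rxn, dtype=np.intp)
        self._hill_sp = np.asarray(hill_sp, dtype=np.intp)
        self._hill_Kn = np.asarray(hill_K, dtype=float) ** np.asarray(
            hill_n, dtype=float
        )
        self._hill_n = np.asarray(hill_n, dtype=float)
        self._hill_inh = np.asarray(hill_inh, dtype=bool)

        self.stoich = network.stoichiometry_matrix()
        self.clamped = (
            tuple(network.environment_indices()) if clamped is None else clamped
        )
        self._clamp_idx = np.asarray(self.clamped, dtype=np.intp)

    # -- evaluation ------------------------------------------------------

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction fluxes at state ``y`` (nonnegative clipped)."""
        yc = np.maximum(np.asarray(y, dtype=float), 0.0)
        f = self.k.copy()
        if self._lin_rxn.size:
            vals = yc[self._lin_sp]
            if not self._lin_simple:
                vals = vals**self._lin_pow
            np.multiply.at(f, self._lin_rxn, vals)
        if self._hill_rxn.size:
            s = yc[self._hill_sp] ** self._hill_n
            num = np.where(self._hill_inh, self._hill_Kn, s)
            np.multiply.at(f, self._hill_rxn, num / (self._hill_Kn + s))
        return f

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.stoich @ self.fluxes(y)
        if self._clamp_idx.size:
            dy[self._clamp_idx] = 0.0
        return dy

    def secretion_rates(self, y: np.ndarray, product: str) -> float:
        """Total production flux of ``product`` at state ``y``."""
        j = self.network.species_index(product)
        f = self.fluxes(y)
        prod = np.maximum(self.stoich[j], 0.0)
        return float(prod @ f)


def assemble_rhs(network: ModelNetwork, params: ParameterSet) -> CompiledRHS:
    """Build the derivative evaluator for a network and parameter set.

    Raises :class:`~bmecsim.network.ConfigurationError` naming any reaction
    parameter id that does not resolve in ``params``.
    """
    return CompiledRHS(network, params)
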