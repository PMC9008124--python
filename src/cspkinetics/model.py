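"""Mass-action kinetic networks and the FcRn-mediated IgG recycling model.

The built-in model describes intravenous IgG disposition in two compartments:
plasma and the endosomal space of endothelial cells.  IgG enters the endosome
by pinocytosis, where it either binds the neonatal Fc receptor (FcRn) -- which
salvages it and recycles it back to plasma -- or is degraded in the lysosome.
The state vector is

    y = [C_p^IgG, C_e^IgG, C_e^FcRn, C_e^IgG.FcRn]   (nM)

and the network consists of five unidirectional mass-action reactions:

    1.  uptake            plasma IgG -> endosomal IgG        R1 = k1 * C_p^IgG
    2.  degradation       endosomal IgG ->                   R2 = kdeg * C_e^IgG
    3f. association       IgG + FcRn -> IgG.FcRn             R3f = kon * C_e^IgG * C_e^FcRn
    3b. dissociation      IgG.FcRn -> IgG + FcRn             R3b = koff * C_e^IgG.FcRn
    4.  recycling         IgG.FcRn -> FcRn + plasma IgG      R4 = k1 * C_e^IgG.FcRn

with a = Ve/Vp (endosome-to-plasma volume ratio, scaling fluxes that cross the
compartment boundary) and k1 = CLup/Ve.  Total FcRn (free plus complexed) is
conserved: C_e^FcRn + C_e^IgG.FcRn = FcRn0 at all times.

Units are fixed: concentrations in nM, time in h, volumes in L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "Reaction",
    "KineticModel",
    "DEFAULT_PARAMETERS",
    "SPECIES",
    "REACTION_LABELS",
    "build_fcrn_model",
    "load_config",
]

#: Species names, in the fixed state-vector order used throughout the package.
SPECIES = ("C_IgG_p", "C_IgG_e", "C_FcRn_e", "C_IgG_FcRn_e")

#: Reaction labels, in stoichiometric-matrix column order.
REACTION_LABELS = ("1", "2", "3f", "3b", "4")

#: Default (human, wild-type IgG) parameter values.
DEFAULT_PARAMETERS = {
    "Vp": 3.10,        # plasma volume, L
    "Ve": 0.34,        # endosomal volume, L
    "CLup": 0.167,     # pinocytosis/exocytosis clearance, L/h
    "kon": 0.559,      # IgG-FcRn association rate, 1/(nM h)
    "koff": 23.9,      # IgG-FcRn dissociation rate, 1/h
    "kdeg": 25.0,      # endosomal degradation rate, 1/h
    "FcRn0": 4.98e4,   # total endosomal FcRn, nM
    "Dose": 24.0e4,    # IV dose, nmol
}

# Negative concentrations within this band (in nM) are clamped to zero for
# rate evaluation; beyond it they are an error.  Stiff solvers can undershoot.
NEGATIVE_TOL = 1e-6


@dataclass(frozen=True)
class ParameterSet:
    """Parameters of the FcRn-IgG recycling model (nM, h, L units).

    The derived quantities ``a = Ve/Vp`` and ``k1 = CLup/Ve`` are recomputed
    properties, never stored.
    """

    Vp: float = DEFAULT_PARAMETERS["Vp"]
    Ve: float = DEFAULT_PARAMETERS["Ve"]
    CLup: float = DEFAULT_PARAMETERS["CLup"]
    kon: float = DEFAULT_PARAMETERS["kon"]
    koff: float = DEFAULT_PARAMETERS["koff"]
    kdeg: float = DEFAULT_PARAMETERS["kdeg"]
    FcRn0: float = DEFAULT_PARAMETERS["FcRn0"]
    Dose: float = DEFAULT_PARAMETERS["Dose"]

    def __post_init__(self) -> None:
        for name in ("Vp", "Ve", "CLup", "kon", "koff", "kdeg", "FcRn0", "Dose"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")

    @property
    def a(self) -> float:
        """Endosome-to-plasma volume ratio Ve/Vp (dimensionless)."""
        return self.Ve / self.Vp

    @property
    def k1(self) -> float:
        """Pinocytosis rate constant CLup/Ve (1/h)."""
        return self.CLup / self.Ve

    def replace(self, **changes) -> "ParameterSet":
        d = self.as_dict()
        d.update(changes)
        return ParameterSet(**d)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in DEFAULT_PARAMETERS}


@dataclass(frozen=True)
class Reaction:
    """One unidirectional mass-action reaction.

    ``order`` is 1 or 2; ``reactants`` holds the indices of the species whose
    concentrations multiply the rate constant ``k``.  ``stoich`` is the signed
    stoichiometric column (length N), which may carry non-integer entries for
    fluxes crossing a compartment boundary.
    """

    label: str
    stoich: tuple
    k: float
    reactants: tuple

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise ValueError("only first- and second-order mass action supported")
        if self.k < 0.0:
            raise ValueError(f"rate constant of reaction {self.label} must be >= 0")

    def rate(self, y: np.ndarray) -> float:
        r = self.k
        for i in self.reactants:
            r *= y[i]
        return r


@dataclass
class KineticModel:
    """A mass-action network: species, reactions, parameters, conserved moieties.

    ``conserved`` is a list of ``(coefficients, total)`` pairs; each coefficient
    vector lies in the left null space of the stoichiometric matrix.
    """

    species: tuple
    reactions: tuple
    params: ParameterSet
    y0: np.ndarray
    conserved: list = field(default_factory=list)

    def __post_init__(self) -> None:
        S = self.stoichiometric_matrix()
        for coeffs, _total in self.conserved:
            if not np.allclose(np.asarray(coeffs) @ S, 0.0, atol=1e-12):
                raise ValueError("conserved coefficient vector is not in the left null space")

    # -- structural accessors -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reaction_labels(self) -> tuple:
        return tuple(r.label for r in self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        """N x K matrix whose k-th column is the k-th stoichiometric vector."""
        return np.column_stack([np.asarray(r.stoich, dtype=float) for r in self.reactions])

    # -- state handling -------------------------------------------------------

    def _clamp(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_species,):
            raise ValueError(f"state must have length {self.n_species}, got shape {y.shape}")
        if np.any(y < -NEGATIVE_TOL):
            raise ValueError(f"state has negative components beyond tolerance: {y}")
        return np.maximum(y, 0.0)

    # -- rate laws and derivatives -------------------------------------------

    def reaction_rates(self, y) -> np.ndarray:
        """Per-reaction rate vector R (nM/h) at state y."""
        y = self._clamp(y)
        return np.array([r.rate(y) for r in self.reactions])

    def rhs(self, y) -> np.ndarray:
        """Time derivative g(y) = S R(y) (nM/h)."""
        return self.stoichiometric_matrix() @ self.reaction_rates(y)

    def rate_gradients(self, y) -> np.ndarray:
        """K x N matrix of rate gradients dR^k/dy."""
        y = self._clamp(y)
        grads = np.zeros((self.n_reactions, self.n_species))
        for k, r in enumerate(self.reactions):
            for i in r.reactants:
                g = r.k
                for j in r.reactants:
                    if j != i:
                        g *= y[j]
                grads[k, i] += g
        return grads

    def jacobian(self, y) -> np.ndarray:
        """Analytic Jacobian dg/dy = sum_k S_k (dR^k/dy)^T (1/h)."""
        return self.stoichiometric_matrix() @ self.rate_gradients(y)


def build_fcrn_model(params: ParameterSet | None = None) -> KineticModel:
    """Instantiate the FcRn-IgG recycling network.

    The initial condition places the whole dose in plasma and all FcRn free:
    y(0) = [Dose/Vp, 0, FcRn0, 0].
    """
    p = params if params is not None else ParameterSet()
    a, k1 = p.a, p.k1
    reactions = (
        Reaction("1", (-a, 1.0, 0.0, 0.0), k1, (0,)),
        Reaction("2", (0.0, -1.0, 0.0, 0.0), p.kdeg, (1,)),
        Reaction("3f", (0.0, -1.0, -1.0, 1.0), p.kon, (1, 2)),
        Reaction("3b", (0.0, 1.0, 1.0, -1.0), p.koff, (3,)),
        Reaction("4", (a, 0.0, 1.0, -1.0), k1, (3,)),
    )
    y0 = np.array([p.Dose / p.Vp, 0.0, p.FcRn0, 0.0])
    conserved = [(np.array([0.0, 0.0, 1.0, 1.0]), p.FcRn0)]
    return KineticModel(SPECIES, reactions, p, y0, conserved)


def load_config(path) -> ParameterSet:
    """Read a YAML parameter file; unspecified keys take the default values."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - set(DEFAULT_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameter keys in config: {sorted(unknown)}")
    merged = dict(DEFAULT_PARAMETERS)
    for key, value in doc.items():
        try:
            # YAML 1.1 parses e.g. "1.0e4" (no signed exponent) as a string
            merged[key] = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"parameter {key} is not numeric: {value!r}") from exc
    return ParameterSet(**merged)
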