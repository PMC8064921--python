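"""Path analysis on a correlation matrix.

A path diagram is a recursive (acyclic) system of standardized linear
equations. For each endogenous variable y with predictor set X the
standardized path coefficients b solve the normal equations

    R_XX b = r_Xy

where R_XX is the predictor correlation block and r_Xy the vector of
predictor-response correlations. The residual variance of y is
1 - b' r_Xy, so the implied R² is b' r_Xy. Direct, indirect, and total
effects follow Wright's tracing rules restricted to directed chains:
the indirect effect of s on t is the sum over all directed paths
s -> ... -> t of length >= 2 of the product of coefficients along the
path, and total = direct + indirect.

This is equivalent to a recursive structural equation model with
uncorrelated residuals fitted by OLS per equation; no latent variables
are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CollinearityError, InvalidArgumentError

#: Endogenous variable -> predictors for the study's integrated diagram:
#: canopy growth rate, flowering date and light extinction drive light
#: interception; canopy growth and leaf area drive extinction; phenology,
#: water-use efficiency and photosynthesis drive RUE and HI; and grain
#: yield is decomposed into the three efficiencies plus flowering date.
DEFAULT_DIAGRAM_SPEC: dict[str, list[str]] = {
    "Ei": ["AGR40", "R1", "K"],
    "K": ["AGR40", "LAI"],
    "RUE": ["R5", "iWUE", "RL", "K", "A", "LAI", "AGR40"],
    "HI": ["A", "SFL", "AGR40", "RL", "R5"],
    "GY": ["HI", "RUE", "Ei", "R1"],
}


@dataclass(frozen=True)
class PathDiagram:
    """Directed acyclic diagram: endogenous variable -> ordered predictors."""

    parents: dict[str, list[str]]

    def __post_init__(self):
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise InvalidArgumentError(f"path diagram contains a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables())
        for child, preds in self.parents.items():
            for p in preds:
                g.add_edge(p, child)
        return g

    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for child, preds in self.parents.items():
            for v in [*preds, child]:
                seen.setdefault(v)
        return list(seen)


def default_diagram() -> PathDiagram:
    return PathDiagram({k: list(v) for k, v in DEFAULT_DIAGRAM_SPEC.items()})


@dataclass
class PathResult:
    coefficients: dict[tuple[str, str], float]  # (endogenous, predictor) -> b
    residual_variance: dict[str, float]
    indirect: dict[tuple[str, str], list[tuple[tuple[str, ...], float]]] = field(
        default_factory=dict
    )
    total: dict[tuple[str, str], float] = field(default_factory=dict)

    def r_squared(self, endogenous: str) -> float:
        return 1.0 - self.residual_variance[endogenous]

    def coefficient_frame(self) -> pd.DataFrame:
        rows = [
            {"endogenous": y, "predictor": x, "coefficient": b}
            for (y, x), b in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def _validate_corr(corr: pd.DataFrame) -> pd.DataFrame:
    values = corr.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise InvalidArgumentError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise InvalidArgumentError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-8):
        raise InvalidArgumentError("correlation matrix must have unit diagonal")
    if np.any(np.abs(values) > 1.0 + 1e-8):
        raise InvalidArgumentError("correlation entries must lie in [-1, 1]")
    return corr


def path_coefficients(corr: pd.DataFrame, diagram: PathDiagram) -> PathResult:
    """Solve the standardized normal equations for every endogenous variable."""
    corr = _validate_corr(corr)
    missing = set(diagram.variables()) - set(corr.index)
    if missing:
        raise InvalidArgumentError(
            f"diagram variables absent from correlation matrix: {sorted(missing)}"
        )
    coefficients: dict[tuple[str, str], float] = {}
    residual_variance: dict[str, float] = {}
    for y, preds in diagram.parents.items():
        r_xx = corr.loc[preds, preds].to_numpy(dtype=float)
        r_xy = corr.loc[preds, y].to_numpy(dtype=float)
        # reciprocal condition number guards against a singular predictor block
        if np.linalg.cond(r_xx) > 1e10:
            raise CollinearityError(
                f"predictor set for {y!r} is collinear: {preds}"
            )
        b = np.linalg.solve(r_xx, r_xy)
        for x, bx in zip(preds, b):
            coefficients[(y, x)] = float(bx)
        residual_variance[y] = float(1.0 - b @ r_xy)
    return effect_decomposition(
        PathResult(coefficients, residual_variance), diagram
    )


def effect_decomposition(result: PathResult, diagram: PathDiagram) -> PathResult:
    """Populate per-path indirect contributions and total effects.

    The indirect effect of source s on target t sums, over every directed
    path s -> ... -> t with at least one intermediate node, the product of
    the path coefficients along the path.
    """
    g = diagram.graph()
    variables = diagram.variables()
    indirect: dict[tuple[str, str], list[tuple[tuple[str, ...], float]]] = {}
    total: dict[tuple[str, str], float] = {}
    for s in variables:
        for t in variables:
            if s == t:
                continue
            contributions = []
            for path in nx.all_simple_paths(g, s, t):
                if len(path) < 3:
                    continue
                prod = 1.0
                for a, b in zip(path, path[1:]):
                    prod *= result.coefficients[(b, a)]
                contributions.append((tuple(path), prod))
            direct = result.coefficients.get((t, s), 0.0)
            ind = sum(c for _, c in contributions)
            if contributions or (t, s) in result.coefficients:
                indirect[(s, t)] = contributions
                total[(s, t)] = direct + ind
    result.indirect = indirect
    result.total = total
    return result


def indirect_effect(result: PathResult, source: str, target: str) -> float:
    return sum(c for _, c in result.indirect.get((source, target), []))


def implied_correlation_check(
    result: PathResult, diagram: PathDiagram, corr: pd.DataFrame
) -> pd.DataFrame:
    """Report |reconstructed - observed| correlations between each endogenous
    variable and every other variable.

    For variable y with coefficients b over predictors X, the model
    reconstructs r_vy = sum_j b_j r_vj for any v. For v in X this is exact
    by the normal equations; for other v the discrepancy diagnoses omitted
    predictors.
    """
    rows = []
    for y, preds in diagram.parents.items():
        b = np.array([result.coefficients[(y, x)] for x in preds])
        for v in corr.index:
            if v == y:
                continue
            reconstructed = float(b @ corr.loc[preds, v].to_numpy(dtype=float))
            observed = float(corr.loc[v, y])
            rows.append(
                {
                    "endogenous": y,
                    "variable": v,
                    "is_parent": v in preds,
                    "reconstructed": reconstructed,
                    "observed": observed,
                    "discrepancy": abs(reconstructed - observed),
                }
            )
    return pd.DataFrame(rows)
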