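"""Thin mixed-integer linear model layer over scipy's HiGHS backend.

Variables are all integer-domain (binaries are integers bounded to [0, 1]);
constraints are two-sided linear inequalities.  The model can be solved via
``scipy.optimize.milp`` or serialized to CPLEX LP format for inspection
with an external solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

INF = float("inf")


@dataclass
class MilpModel:
    name: str = "model"
    var_names: list[str] = field(default_factory=list)
    lb: list[float] = field(default_factory=list)
    ub: list[float] = field(default_factory=list)
    # constraints as (coeffs {var_index: coef}, lower, upper, name)
    constraints: list[tuple[dict[int, float], float, float, str]] = field(
        default_factory=list
    )
    objective: dict[int, float] = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    def add_var(self, name: str, lb: float, ub: float) -> int:
        idx = len(self.var_names)
        self.var_names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        return idx

    def add_binary(self, name: str) -> int:
        return self.add_var(name, 0, 1)

    def add_constraint(
        self,
        coeffs: dict[int, float],
        lower: float = -INF,
        upper: float = INF,
        name: str = "",
    ) -> None:
        self.constraints.append((coeffs, lower, upper, name))

    def set_objective(self, coeffs: dict[int, float]) -> None:
        self.objective = dict(coeffs)

    # -- solving ---------------------------------------------------------
    def solve(self, time_limit: float | None = None) -> tuple[str, np.ndarray | None, float]:
        """Solve to proven optimality; returns (status, values, objective)."""
        n = self.n_vars
        c = np.zeros(n)
        for i, coef in self.objective.items():
            c[i] = coef
        rows, cols, vals = [], [], []
        lo = np.empty(len(self.constraints))
        hi = np.empty(len(self.constraints))
        for r, (coeffs, lower, upper, _) in enumerate(self.constraints):
            lo[r], hi[r] = lower, upper
            for i, coef in coeffs.items():
                rows.append(r)
                cols.append(i)
                vals.append(coef)
        options = {}
        if time_limit is not None:
            options["time_limit"] = time_limit
        kwargs = dict(
            c=c,
            integrality=np.ones(n),
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
            options=options,
        )
        if self.constraints:
            a = sparse.csc_array(
                (vals, (rows, cols)), shape=(len(self.constraints), n)
            )
            kwargs["constraints"] = LinearConstraint(a, lo, hi)
        res = milp(**kwargs)
        if res.status == 0:
            return "optimal", res.x, float(res.fun)
        if res.status == 2:
            return "infeasible", None, float("nan")
        return "error", getattr(res, "x", None), float("nan")

    # -- LP export -------------------------------------------------------
    def to_lp(self, path) -> None:
        """Write the model in CPLEX LP format (all variables general integer)."""

        def term(coef: float, name: str) -> str:
            sign = "+" if coef >= 0 else "-"
            return f"{sign} {abs(coef):g} {name}"

        with open(path, "w") as fh:
            fh.write(f"\\ {self.name}\nMinimize\n obj: ")
            parts = [
                term(c, self.var_names[i])
                for i, c in sorted(self.objective.items())
                if c != 0
            ]
            fh.write(" ".join(parts) if parts else "0 " + self.var_names[0])
            fh.write("\nSubject To\n")
            cnum = 0
            for coeffs, lower, upper, name in self.constraints:
                expr = " ".join(
                    term(c, self.var_names[i]) for i, c in sorted(coeffs.items())
                )
                label = name or f"c{cnum}"
                if lower == upper:
                    fh.write(f" {label}: {expr} = {lower:g}\n")
                else:
                    if upper < INF:
                        fh.write(f" {label}_u: {expr} <= {upper:g}\n")
                    if lower > -INF:
                        fh.write(f" {label}_l: {expr} >= {lower:g}\n")
                cnum += 1
            fh.write("Bounds\n")
            for i, name in enumerate(self.var_names):
                fh.write(f" {self.lb[i]:g} <= {name} <= {self.ub[i]:g}\n")
            fh.write("Generals\n")
            for name in self.var_names:
                fh.write(f" {name}\n")
            fh.write("End\n")
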