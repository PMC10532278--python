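"""Symbolic SEM structure and a lavaan-style model syntax parser.

The supported syntax subset:

* ``F =~ X1 + X2 + X3`` — measurement model (factor loadings),
* ``A ~~ B`` — (co)variance between two factors or two indicators,
* ``FY ~ FX`` — structural regression among factors,
* a numeric prefix fixes a value, e.g. ``F =~ 1*X1`` or ``F ~~ 0.5*G``,
* one statement per line, ``#`` starts a comment.

Free parameters carry lavaan-style labels (``F=~X2``, ``FX~~FY``, ``X1~~X1``,
``FY~FX``) that are used everywhere downstream: invariance lists, DIF curves,
curve summaries and output tables.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = ["Parameter", "ModelSpec", "parse_model_syntax", "ModelSyntaxError"]

# matrix codes
LAMBDA, BETA, PHI, PSI = "lambda", "beta", "phi", "psi"


class ModelSyntaxError(ValueError):
    """Raised for malformed or inconsistent model syntax."""


@dataclass(frozen=True)
class Parameter:
    """One entry of Λ, B, Φ or Ψ.

    ``row``/``col`` index indicators for ``lambda`` (row) and ``psi``, and
    factors for ``beta``/``phi``; ``col`` of ``lambda`` indexes factors.
    Symmetric matrices (Φ, Ψ) store the entry once with ``row <= col`` in
    declaration order of the variable lists.
    """

    label: str
    matrix: str
    row: int
    col: int
    free: bool
    value: float = math.nan

    @property
    def is_variance(self) -> bool:
        return self.matrix in (PHI, PSI) and self.row == self.col


@dataclass
class ModelSpec:
    """Symbolic structure of a (confirmatory) SEM covariance model."""

    indicators: list[str]
    factors: list[str]
    parameters: list[Parameter] = field(default_factory=list)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def free_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters if p.free]

    @property
    def free_labels(self) -> list[str]:
        return [p.label for p in self.parameters if p.free]

    def parameter(self, label: str) -> Parameter:
        for p in self.parameters:
            if p.label == label:
                return p
        raise KeyError(f"no parameter with label {label!r}")

    @property
    def has_structural(self) -> bool:
        return any(p.matrix == BETA for p in self.parameters)

    def validate(self) -> None:
        seen = set()
        for p in self.parameters:
            key = (p.matrix, p.row, p.col)
            if key in seen:
                raise ModelSyntaxError(f"duplicate parameter entry {key}")
            seen.add(key)
        for k, f in enumerate(self.factors):
            if not any(p.matrix == LAMBDA and p.col == k for p in self.parameters):
                raise ModelSyntaxError(f"factor {f!r} has zero indicators")
        _check_acyclic(self)


def _check_acyclic(spec: ModelSpec) -> None:
    """B must be nilpotent (acyclic path diagram) so that I - B is invertible."""
    edges = {}
    for p in spec.parameters:
        if p.matrix == BETA:
            edges.setdefault(p.row, set()).add(p.col)  # dep -> predictors
    state: dict[int, int] = {}

    def visit(k: int) -> None:
        state[k] = 1
        for m in edges.get(k, ()):
            if state.get(m) == 1:
                raise ModelSyntaxError("cyclic structural model (B has a cycle)")
            if state.get(m, 0) == 0:
                visit(m)
        state[k] = 2

    for k in list(edges):
        if state.get(k, 0) == 0:
            visit(k)


_TERM_RE = re.compile(r"^(?:([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*\*\s*)?([A-Za-z_][\w.]*)$")


def _parse_term(term: str, line: str) -> tuple[float | None, str]:
    m = _TERM_RE.match(term.strip())
    if not m:
        raise ModelSyntaxError(f"cannot parse term {term!r} in line {line!r}")
    coef = float(m.group(1)) if m.group(1) is not None else None
    return coef, m.group(2)


def parse_model_syntax(text: str, auto_fix_first: bool = True) -> ModelSpec:
    """Parse a lavaan-style model string into a :class:`ModelSpec`.

    Parameters
    ----------
    text
        Model syntax; operators ``=~`` (loadings), ``~~`` ((co)variances) and
        ``~`` (regressions among factors).
    auto_fix_first
        If a factor has no fixed loading, fix its first loading at 1
        (the usual marker-indicator identification).

    Notes
    -----
    Residual variances of all indicators and variances of all factors are
    added as free parameters unless stated explicitly.  Covariances between
    exogenous factors are free by default; covariances involving an
    endogenous factor (one that appears on the left of ``~``) are fixed at 0
    unless stated.
    """
    loadings: dict[str, list[tuple[float | None, str]]] = {}
    covs: list[tuple[str, str, float | None]] = []
    regs: list[tuple[str, str, float | None]] = []

    for raw in text.replace(";", "\n").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            fac = lhs.strip()
            if not fac.isidentifier():
                raise ModelSyntaxError(f"bad factor name in line {line!r}")
            items = [_parse_term(t, line) for t in rhs.split("+")]
            loadings.setdefault(fac, []).extend(items)
        elif "~~" in line:
            lhs, rhs = line.split("~~", 1)
            for coef, name in (_parse_term(t, line) for t in rhs.split("+")):
                covs.append((lhs.strip(), name, coef))
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
            for coef, name in (_parse_term(t, line) for t in rhs.split("+")):
                regs.append((lhs.strip(), name, coef))
        else:
            raise ModelSyntaxError(f"no operator (=~, ~~, ~) in line {line!r}")

    if not loadings:
        raise ModelSyntaxError("model defines no factors (no =~ statements)")

    factors = list(loadings)
    indicators: list[str] = []
    for items in loadings.values():
        for _, name in items:
            if name in factors:
                raise ModelSyntaxError(f"{name!r} used both as factor and indicator")
            if name not in indicators:
                indicators.append(name)

    i_index = {v: i for i, v in enumerate(indicators)}
    f_index = {v: k for k, v in enumerate(factors)}

    params: list[Parameter] = []
    entry_map: dict[tuple[str, int, int], int] = {}

    def add(label: str, matrix: str, row: int, col: int, free: bool, value: float = math.nan):
        key = (matrix, row, col)
        if key in entry_map:
            old = params[entry_map[key]]
            if old.free != free or (not free and not math.isclose(old.value, value)):
                raise ModelSyntaxError(f"conflicting duplicate statements for {label!r}")
            return  # duplicate statements merged
        entry_map[key] = len(params)
        params.append(Parameter(label, matrix, row, col, free, value))

    # loadings
    for fac, items in loadings.items():
        k = f_index[fac]
        fixed_any = any(c is not None for c, _ in items)
        for pos, (coef, name) in enumerate(items):
            i = i_index[name]
            label = f"{fac}=~{name}"
            if coef is not None:
                add(label, LAMBDA, i, k, free=False, value=coef)
            elif auto_fix_first and not fixed_any and pos == 0:
                add(label, LAMBDA, i, k, free=False, value=1.0)
            else:
                add(label, LAMBDA, i, k, free=True)

    # regressions (factors only)
    endogenous: set[str] = set()
    for dep, pred, coef in regs:
        if dep not in f_index or pred not in f_index:
            raise ModelSyntaxError(
                f"regression {dep!r} ~ {pred!r}: both sides must be factors")
        endogenous.add(dep)
        label = f"{dep}~{pred}"
        if coef is not None:
            add(label, BETA, f_index[dep], f_index[pred], free=False, value=coef)
        else:
            add(label, BETA, f_index[dep], f_index[pred], free=True)

    # explicit (co)variances
    for a, b, coef in covs:
        if a in f_index and b in f_index:
            r, c = sorted((f_index[a], f_index[b]))
            la, lb = factors[r], factors[c]
            add(f"{la}~~{lb}", PHI, r, c, free=coef is None,
                value=coef if coef is not None else math.nan)
        elif a in i_index and b in i_index:
            r, c = sorted((i_index[a], i_index[b]))
            la, lb = indicators[r], indicators[c]
            add(f"{la}~~{lb}", PSI, r, c, free=coef is None,
                value=coef if coef is not None else math.nan)
        else:
            raise ModelSyntaxError(
                f"covariance {a!r} ~~ {b!r}: mixed or unknown variable names")

    # default factor variances, exogenous factor covariances
    for fac, k in f_index.items():
        if (PHI, k, k) not in entry_map:
            add(f"{fac}~~{fac}", PHI, k, k, free=True)
    for k in range(len(factors)):
        for m in range(k + 1, len(factors)):
            if (PHI, k, m) in entry_map:
                continue
            if factors[k] in endogenous or factors[m] in endogenous:
                continue  # fixed 0: implicit (entry absent)
            add(f"{factors[k]}~~{factors[m]}", PHI, k, m, free=True)

    # default residual variances
    for v, i in i_index.items():
        if (PSI, i, i) not in entry_map:
            add(f"{v}~~{v}", PSI, i, i, free=True)

    spec = ModelSpec(indicators=indicators, factors=factors, parameters=params)
    spec.validate()
    return spec
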