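"""Path-model specification in RAM form.

A structural model over variables v = (observed, latent) is held as three
parameter matrices:

* ``A`` — directed paths (regressions, factor loadings); ``A[i, j]`` is the
  path from variable ``j`` into variable ``i``.
* ``S`` — symmetric (co)variances of exogenous terms and residuals.
* ``M`` — means / intercepts.

Each declared entry is either a fixed numeric value or a free parameter
label; entries sharing a label are constrained equal.  Undeclared entries
are fixed at zero.  The model-implied moments over the observed variables
are obtained from the usual reduced form

    Sigma = F (I - A)^-1 S (I - A)^-T F^T,      mu = F (I - A)^-1 M,

where ``F`` selects the observed rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = ["Entry", "PathSpec", "SpecificationError"]


class SpecificationError(ValueError):
    """Raised when a path specification is malformed or inconsistent."""


@dataclass(frozen=True)
class Entry:
    """One declared cell of A, S or M.

    Exactly one of ``value`` (fixed) and ``label`` (free) is set; ``start``
    optionally seeds the optimizer for free entries.
    """

    matrix: str          # 'A' | 'S' | 'M'
    row: str
    col: str | None      # None for M entries
    value: float | None = None
    label: str | None = None
    start: float | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.label is None):
            raise SpecificationError(
                f"entry {self.matrix}[{self.row},{self.col}] must have exactly "
                "one of a fixed value or a free label"
            )
        if self.matrix not in ("A", "S", "M"):
            raise SpecificationError(f"unknown matrix {self.matrix!r}")

    @property
    def is_free(self) -> bool:
        return self.label is not None


@dataclass
class PathSpec:
    """A RAM path specification with free/fixed/equality-labelled entries."""

    observed: list[str]
    latent: list[str] = field(default_factory=list)
    entries: list[Entry] = field(default_factory=list)

    # ------------------------------------------------------------------ build
    def add_path(self, src: str, dst: str, *, value: float | None = None,
                 label: str | None = None, start: float | None = None) -> "PathSpec":
        """Directed path ``dst <- src`` (an entry of A)."""
        self.entries.append(Entry("A", dst, src, value, label, start))
        return self

    def add_cov(self, a: str, b: str | None = None, *, value: float | None = None,
                label: str | None = None, start: float | None = None) -> "PathSpec":
        """(Co)variance entry of S; ``b`` defaults to ``a`` (a variance)."""
        self.entries.append(Entry("S", a, b if b is not None else a, value, label, start))
        return self

    def add_mean(self, var: str, *, value: float | None = None,
                 label: str | None = None, start: float | None = None) -> "PathSpec":
        self.entries.append(Entry("M", var, None, value, label, start))
        return self

    # -------------------------------------------------------------- inspection
    @property
    def variables(self) -> list[str]:
        return list(self.observed) + list(self.latent)

    def free_labels(self) -> list[str]:
        """Distinct free labels in order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.is_free and e.label not in seen:
                seen[e.label] = None
        return list(seen)

    def has_variable(self, name: str) -> bool:
        return name in self.observed or name in self.latent

    def declared(self, matrix: str, row: str, col: str | None) -> Entry | None:
        for e in self.entries:
            if e.matrix != matrix:
                continue
            if matrix == "S":
                if {e.row, e.col} == {row, col}:
                    return e
            elif e.row == row and e.col == col:
                return e
        return None

    def validate(self) -> None:
        names = self.variables
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SpecificationError(f"duplicate variable names: {dup}")
        for e in self.entries:
            for v in (e.row,) + (() if e.col is None else (e.col,)):
                if v not in names:
                    raise SpecificationError(
                        f"entry {e.matrix}[{e.row},{e.col}] references unknown variable {v!r}"
                    )
        # S must not declare the same unordered pair twice with conflicting roles
        pairs: dict[frozenset, Entry] = {}
        for e in self.entries:
            if e.matrix != "S":
                continue
            key = frozenset((e.row, e.col))
            if key in pairs:
                raise SpecificationError(
                    f"covariance S[{e.row},{e.col}] declared more than once"
                )
            pairs[key] = e
        for m in ("A", "M"):
            seen: set = set()
            for e in self.entries:
                if e.matrix != m:
                    continue
                key = (e.row, e.col)
                if key in seen:
                    raise SpecificationError(f"{m}[{e.row},{e.col}] declared more than once")
                seen.add(key)
        if not self.observed:
            raise SpecificationError("specification has no observed variables")

    # ------------------------------------------------------------ compilation
    def compile(self) -> "CompiledSpec":
        self.validate()
        return CompiledSpec(self)

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        def ser(e: Entry) -> dict:
            d: dict = {"from": e.col, "to": e.row} if e.matrix == "A" else (
                {"a": e.row, "b": e.col} if e.matrix == "S" else {"var": e.row})
            if e.is_free:
                d["label"] = e.label
                if e.start is not None:
                    d["start"] = e.start
            else:
                d["value"] = e.value
            return d

        return {
            "observed": list(self.observed),
            "latent": list(self.latent),
            "paths": [ser(e) for e in self.entries if e.matrix == "A"],
            "covariances": [ser(e) for e in self.entries if e.matrix == "S"],
            "means": [ser(e) for e in self.entries if e.matrix == "M"],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathSpec":
        spec = cls(observed=list(d["observed"]), latent=list(d.get("latent", [])))
        for p in d.get("paths", []):
            spec.add_path(p["from"], p["to"], value=p.get("value"),
                          label=p.get("label"), start=p.get("start"))
        for c in d.get("covariances", []):
            spec.add_cov(c["a"], c["b"], value=c.get("value"),
                         label=c.get("label"), start=c.get("start"))
        for m in d.get("means", []):
            spec.add_mean(m["var"], value=m.get("value"),
                          label=m.get("label"), start=m.get("start"))
        return spec

    def to_json(self, path=None, **kw) -> str | None:
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is None:
            return s
        with open(path, "w") as fh:
            fh.write(s)
        return None

    @classmethod
    def from_json(cls, source: str) -> "PathSpec":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def to_yaml(self, path=None) -> str | None:
        s = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return s
        with open(path, "w") as fh:
            fh.write(s)
        return None

    @classmethod
    def from_yaml(cls, source: str) -> "PathSpec":
        d = yaml.safe_load(source)
        if isinstance(d, str):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)


class CompiledSpec:
    """Index-based realization of a PathSpec for fast moment evaluation."""

    def __init__(self, spec: PathSpec):
        self.spec = spec
        names = spec.variables
        self.names = names
        self.index = {v: i for i, v in enumerate(names)}
        self.n_obs = len(spec.observed)
        self.nv = len(names)
        self.labels = spec.free_labels()
        self.label_index = {l: i for i, l in enumerate(self.labels)}
        self.npar = len(self.labels)

        nv = self.nv
        self.A0 = np.zeros((nv, nv))
        self.S0 = np.zeros((nv, nv))
        self.M0 = np.zeros(nv)
        # free-entry index lists: (param_idx, i, j)
        a_free: list[tuple[int, int, int]] = []
        s_free: list[tuple[int, int, int]] = []
        m_free: list[tuple[int, int]] = []
        self.starts: dict[str, float] = {}
        for e in spec.entries:
            i = self.index[e.row]
            j = self.index[e.col] if e.col is not None else -1
            if e.matrix == "A":
                if e.is_free:
                    a_free.append((self.label_index[e.label], i, j))
                else:
                    self.A0[i, j] = e.value
            elif e.matrix == "S":
                if e.is_free:
                    s_free.append((self.label_index[e.label], i, j))
                else:
                    self.S0[i, j] = e.value
                    self.S0[j, i] = e.value
            else:
                if e.is_free:
                    m_free.append((self.label_index[e.label], i))
                else:
                    self.M0[i] = e.value
            if e.is_free and e.start is not None:
                self.starts.setdefault(e.label, e.start)
        self.a_free = a_free
        self.s_free = s_free
        self.m_free = m_free
        self.has_free_a = bool(a_free)

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        for k, i, j in self.a_free:
            A[i, j] = theta[k]
        for k, i, j in self.s_free:
            S[i, j] = theta[k]
            S[j, i] = theta[k]
        for k, i in self.m_free:
            M[i] = theta[k]
        return A, S, M

    def implied_moments(self, theta: np.ndarray, include_latent: bool = False):
        """Model-implied (Sigma, mu); observed block only unless requested."""
        A, S, M = self.matrices(theta)
        ImA = np.eye(self.nv) - A
        try:
            B = np.linalg.solve(ImA, np.eye(self.nv))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular (I - A) at the supplied parameter values; the "
                "directed-path structure is not solvable"
            ) from exc
        Sigma_all = B @ S @ B.T
        Sigma_all = 0.5 * (Sigma_all + Sigma_all.T)
        mu_all = B @ M
        if include_latent:
            return Sigma_all, mu_all
        k = self.n_obs
        return Sigma_all[:k, :k], mu_all[:k]
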