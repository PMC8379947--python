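"""Declarative path-model specification and its RAM matrix form.

A structural equation model is written in a small text grammar::

    # latent definition: first indicator's loading is fixed to 1 (scale)
    CT ~ fiber + vessel + parenchyma
    # directed paths: each predictor contributes one free coefficient
    p75 <- pmin + CT
    # fixed variance (e.g. an error variance pinned to zero)
    var(fiber) = 0
    # free residual covariance between two error terms
    cov(vessel, parenchyma) = free

Every declared variable receives a free (residual) variance unless a
``var()`` line fixes it.  The model is held in :class:`ModelSpec` and
compiled to RAM form (directed-effects matrix A, residual-covariance
matrix S, observed-row selector F) by :func:`build_ram`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "RamMatrices",
    "ModelSpecError",
    "parse_model_spec",
    "build_ram",
    "independence_model",
    "saturated_model",
]


class ModelSpecError(ValueError):
    """Raised for syntactically or structurally invalid model text."""


@dataclass(frozen=True)
class ModelSpec:
    """A path model: variables, latent definitions, paths, and constraints.

    Attributes
    ----------
    observed : tuple of str
        Observed variable names, in order of first appearance.
    latents : dict
        Latent name -> tuple of indicator names.  The first indicator's
        loading is fixed to 1.0 (the latent's scale constraint); the rest
        are free.
    paths : tuple of (src, dst, value)
        Directed effects src -> dst; ``value`` is None for a free
        coefficient or a float for a fixed one.
    error_covs : tuple of (a, b, value)
        Residual covariances; None means free.
    variances : dict
        Variable -> None (free) or float (fixed value).
    """

    observed: tuple[str, ...]
    latents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    paths: tuple[tuple[str, str, float | None], ...] = ()
    error_covs: tuple[tuple[str, str, float | None], ...] = ()
    variances: dict[str, float | None] = field(default_factory=dict)

    # -- bookkeeping -------------------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        """All variables, observed first, then latents."""
        return tuple(self.observed) + tuple(self.latents)

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    def free_parameters(self) -> list[tuple[str, str, str]]:
        """Deterministic ordering of the free-parameter vector.

        Returns a list of (kind, i, j) labels: kind in
        {"loading", "path", "cov", "var"}.  Fixed entries never appear.
        """
        params: list[tuple[str, str, str]] = []
        for lat, inds in self.latents.items():
            for ind in inds[1:]:  # first loading carries the scale, fixed 1
                params.append(("loading", ind, lat))
        for src, dst, val in self.paths:
            if val is None:
                params.append(("path", src, dst))
        for a, b, val in self.error_covs:
            if val is None:
                params.append(("cov", a, b))
        for v in self.variables:
            if self.variances.get(v, None) is None:
                params.append(("var", v, v))
        return params

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_parameters())

    @property
    def df(self) -> int:
        """Model degrees of freedom: p(p+1)/2 moments minus K."""
        p = self.n_observed
        return p * (p + 1) // 2 - self.k

    # -- editing operations used by the inference layer --------------------
    def drop_path(self, src: str, dst: str) -> "ModelSpec":
        new = tuple(t for t in self.paths if (t[0], t[1]) != (src, dst))
        if len(new) == len(self.paths):
            raise ModelSpecError(f"no path {src} -> {dst} in model")
        return replace(self, paths=new)

    def reverse_path(self, src: str, dst: str) -> "ModelSpec":
        """Invert the direction of one directed path; K is unchanged."""
        out = []
        found = False
        for s, d, v in self.paths:
            if (s, d) == (src, dst):
                out.append((d, s, v))
                found = True
            else:
                out.append((s, d, v))
        if not found:
            raise ModelSpecError(f"no path {src} -> {dst} in model")
        if any(out.count(t) > 1 for t in out):
            raise ModelSpecError("reversal duplicates an existing path")
        return replace(self, paths=tuple(out))

    def drop_variable(self, name: str) -> "ModelSpec":
        """Remove an observed variable, its paths and variance entries."""
        if name not in self.observed:
            raise ModelSpecError(f"{name!r} is not an observed variable")
        for lat, inds in self.latents.items():
            if name in inds:
                if len(inds) - 1 < 2:
                    raise ModelSpecError(
                        f"removing {name!r} leaves latent {lat!r} with "
                        "fewer than 2 indicators (under-identified)"
                    )
                raise ModelSpecError(
                    f"{name!r} is an indicator of latent {lat!r}; "
                    "edit the latent definition instead"
                )
        observed = tuple(v for v in self.observed if v != name)
        if not observed:
            raise ModelSpecError("removal leaves an empty model")
        paths = tuple(t for t in self.paths if name not in t[:2])
        covs = tuple(t for t in self.error_covs if name not in t[:2])
        variances = {v: x for v, x in self.variances.items() if v != name}
        return replace(
            self, observed=observed, paths=paths, error_covs=covs, variances=variances
        )


_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_RE_LATENT = re.compile(rf"^({_NAME})\s*~\s*(.+)$")
_RE_PATH = re.compile(rf"^({_NAME})\s*<-\s*(.+)$")
_RE_VAR = re.compile(rf"^var\(\s*({_NAME})\s*\)\s*=\s*(.+)$")
_RE_COV = re.compile(rf"^cov\(\s*({_NAME})\s*,\s*({_NAME})\s*\)\s*=\s*(.+)$")


def _parse_value(tok: str, where: str) -> float | None:
    tok = tok.strip()
    if tok == "free":
        return None
    try:
        return float(tok)
    except ValueError:
        raise ModelSpecError(f"cannot parse value {tok!r} in {where}") from None


def parse_model_spec(text: str) -> ModelSpec:
    """Parse model text into a validated :class:`ModelSpec`.

    Raises :class:`ModelSpecError` on duplicate paths, undeclared
    variables in constraints, duplicate latent definitions, or a latent
    used as an indicator of itself (cyclic latent definition).
    """
    latents: dict[str, tuple[str, ...]] = {}
    paths: list[tuple[str, str, float | None]] = []
    covs: list[tuple[str, str, float | None]] = []
    fixed_vars: dict[str, float] = {}
    order: list[str] = []  # observed, order of first appearance

    def touch(name: str) -> None:
        if name not in order:
            order.append(name)

    lines = [ln.split("#", 1)[0].strip() for ln in text.splitlines()]
    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        m = _RE_VAR.match(line)
        if m:
            fixed_vars[m.group(1)] = _parse_value(m.group(2), f"line {lineno}")
            touch(m.group(1))
            continue
        m = _RE_COV.match(line)
        if m:
            a, b = m.group(1), m.group(2)
            if a == b:
                raise ModelSpecError(f"line {lineno}: cov() needs two distinct variables")
            covs.append((a, b, _parse_value(m.group(3), f"line {lineno}")))
            touch(a)
            touch(b)
            continue
        m = _RE_LATENT.match(line)
        if m:
            lat, rhs = m.group(1), m.group(2)
            if lat in latents:
                raise ModelSpecError(f"line {lineno}: latent {lat!r} defined twice")
            inds = tuple(s.strip() for s in rhs.split("+"))
            if len(inds) != len(set(inds)):
                raise ModelSpecError(f"line {lineno}: duplicate indicator in {lat!r}")
            if lat in inds:
                raise ModelSpecError(f"line {lineno}: latent {lat!r} indicates itself")
            latents[lat] = inds
            for ind in inds:
                touch(ind)
            continue
        m = _RE_PATH.match(line)
        if m:
            dst, rhs = m.group(1), m.group(2)
            touch(dst)
            for term in rhs.split("+"):
                term = term.strip()
                val: float | None = None
                if "*" in term:
                    coef, term = term.split("*", 1)
                    val = float(coef)
                    term = term.strip()
                if (term, dst) in [(s, d) for s, d, _ in paths]:
                    raise ModelSpecError(
                        f"line {lineno}: path {term} -> {dst} declared twice"
                    )
                paths.append((term, dst, val))
                touch(term)
            continue
        raise ModelSpecError(f"line {lineno}: cannot parse {line!r}")

    # latents indicated by other latents would need a topological check;
    # indicators that are themselves latent names are disallowed outright
    for lat, inds in latents.items():
        for ind in inds:
            if ind in latents:
                raise ModelSpecError(
                    f"latent {lat!r} uses latent {ind!r} as an indicator "
                    "(higher-order latents not supported)"
                )

    observed = tuple(v for v in order if v not in latents)
    declared = set(observed) | set(latents)
    for s, d, _ in paths:
        for v in (s, d):
            if v not in declared:
                raise ModelSpecError(f"undeclared variable {v!r} in path")
    for a, b, _ in covs:
        for v in (a, b):
            if v not in declared:
                raise ModelSpecError(f"undeclared variable {v!r} in cov()")
    for v in fixed_vars:
        if v not in declared:
            raise ModelSpecError(f"undeclared variable {v!r} in var()")
    if len(set((a, b) for a, b, _ in covs)) != len(covs):
        raise ModelSpecError("duplicate cov() declaration")

    variances: dict[str, float | None] = {
        v: fixed_vars.get(v, None) for v in tuple(observed) + tuple(latents)
    }
    return ModelSpec(
        observed=observed,
        latents=latents,
        paths=tuple(paths),
        error_covs=tuple(covs),
        variances=variances,
    )


@dataclass
class RamMatrices:
    """RAM form of a model: Sigma = F (I-A)^-1 S (I-A)^-T F^T.

    ``A`` holds directed effects and factor loadings (row = target,
    column = source), ``S`` residual variances/covariances, ``F`` selects
    the observed rows.  ``theta_map`` lists, for each free parameter in
    :meth:`ModelSpec.free_parameters` order, the matrix ("A" or "S") and
    cell it fills; S entries are mirrored.
    """

    spec: ModelSpec
    names: tuple[str, ...]
    index: dict[str, int]
    a_fixed: np.ndarray
    s_fixed: np.ndarray
    theta_map: list[tuple[str, int, int]]

    @property
    def n_observed(self) -> int:
        return self.spec.n_observed

    @property
    def dim(self) -> int:
        return len(self.names)

    def fill(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, S) at a parameter vector."""
        a = self.a_fixed.copy()
        s = self.s_fixed.copy()
        for val, (mat, i, j) in zip(theta, self.theta_map):
            if mat == "A":
                a[i, j] = val
            else:
                s[i, j] = val
                s[j, i] = val
        return a, s

    def start_values(self, sample_cov: np.ndarray) -> np.ndarray:
        """Default start: sample variances for free variances, 0 for paths,
        1 for free loadings; a latent starts at its scale indicator's
        sample variance."""
        spec = self.spec
        sv = {v: sample_cov[i, i] for i, v in enumerate(spec.observed)}
        for lat, inds in spec.latents.items():
            sv[lat] = 0.5 * sv[inds[0]]
        theta = []
        for kind, i, j in spec.free_parameters():
            if kind == "loading":
                theta.append(1.0)
            elif kind == "path":
                theta.append(0.0)
            elif kind == "cov":
                theta.append(0.0)
            else:
                theta.append(max(sv[i] * 0.5, 1e-3))
        return np.asarray(theta, dtype=float)


def build_ram(spec: ModelSpec) -> RamMatrices:
    """Compile a :class:`ModelSpec` to RAM matrices."""
    names = spec.variables
    index = {v: i for i, v in enumerate(names)}
    m = len(names)
    a = np.zeros((m, m))
    s = np.zeros((m, m))

    # fixed loadings (scale constraints) and fixed paths
    for lat, inds in spec.latents.items():
        a[index[inds[0]], index[lat]] = 1.0
    for src, dst, val in spec.paths:
        if val is not None:
            a[index[dst], index[src]] = val
    for va, vb, val in spec.error_covs:
        if val is not None:
            s[index[va], index[vb]] = val
            s[index[vb], index[va]] = val
    for v, val in spec.variances.items():
        if val is not None:
            s[index[v], index[v]] = val

    # free_parameters stores (kind, src, dst) for paths, (kind, ind, lat)
    # for loadings, (kind, v, v) for variances, (kind, a, b) for covariances
    theta_map: list[tuple[str, int, int]] = []
    for kind, i, j in spec.free_parameters():
        if kind == "path":
            theta_map.append(("A", index[j], index[i]))  # row target, col source
        elif kind == "loading":
            theta_map.append(("A", index[i], index[j]))  # row indicator, col latent
        else:
            theta_map.append(("S", index[i], index[j]))

    return RamMatrices(
        spec=spec, names=names, index=index, a_fixed=a, s_fixed=s, theta_map=theta_map
    )


def independence_model(observed: list[str] | tuple[str, ...]) -> ModelSpec:
    """Baseline model: free variances only, no paths, no covariances."""
    obs = tuple(observed)
    return ModelSpec(observed=obs, variances={v: None for v in obs})


def saturated_model(observed: list[str] | tuple[str, ...]) -> ModelSpec:
    """All variances and all pairwise covariances free; df = 0."""
    obs = tuple(observed)
    covs = tuple(
        (obs[i], obs[j], None) for i in range(len(obs)) for j in range(i + 1, len(obs))
    )
    return ModelSpec(observed=obs, error_covs=covs, variances={v: None for v in obs})
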