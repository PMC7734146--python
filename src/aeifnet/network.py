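"""Random directed network construction: populations, synapse classes, autapses.

The network has two populations (excitatory, inhibitory).  Directed
edges fall into six classes determined entirely by the endpoint labels
and whether the edge is a self-loop:

===========  =============================================  ============
class        meaning                                        conductance
===========  =============================================  ============
``ee``       excitatory -> excitatory                       ``g_e``
``ei``       excitatory -> inhibitory                       ``g_ei``
``ii``       inhibitory -> inhibitory                       ``g_i``
``ie``       inhibitory -> excitatory                       ``g_ie``
``e_aut``    excitatory autapse (self-loop)                 ``g_e_aut``
``i_aut``    inhibitory autapse (self-loop)                 ``g_i_aut``
===========  =============================================  ============

Ordinary synapses are sampled i.i.d. Bernoulli per ordered pair
(self-pairs excluded), so the empirical connection probability
``N_e / (N_exc (N_exc - 1))`` etc. is binomial around the configured
value.  Autapses are an exact fraction of each population: exactly
``round(p_aut * N_pop)`` neurons receive one self-loop, chosen uniformly
without replacement.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import NeuronParams

__all__ = [
    "EDGE_CLASSES",
    "CLASS_TO_CONDUCTANCE",
    "CONDUCTANCE_RANGES",
    "NetworkConfig",
    "NetworkGraph",
    "build_populations",
    "sample_random_edges",
    "assign_autapses",
    "assemble_network",
]

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("ee", "ei", "ii", "ie", "e_aut", "i_aut")
_CODE = {c: i for i, c in enumerate(EDGE_CLASSES)}

#: Edge class -> NetworkConfig conductance field.
CLASS_TO_CONDUCTANCE = {
    "ee": "g_e",
    "ei": "g_ei",
    "ii": "g_i",
    "ie": "g_ie",
    "e_aut": "g_e_aut",
    "i_aut": "g_i_aut",
}

#: Conductance ranges (nS) explored in the reference parameter planes.
CONDUCTANCE_RANGES = {
    "g_e": (0.0, 0.5),
    "g_e_aut": (0.0, 35.0),
    "g_ei": (0.0, 5.0),
    "g_i": (0.0, 2.0),
    "g_i_aut": (0.0, 100.0),
    "g_ie": (0.0, 3.0),
}

# Named RNG streams derived from one master seed, so initial conditions,
# graph wiring, autapse placement and per-neuron heterogeneity can each
# be varied in isolation.
STREAM_GRAPH = 0
STREAM_AUTAPSE = 1
STREAM_INIT = 2
STREAM_HETERO = 3


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Generator for one named substream of a master seed."""
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class NetworkConfig:
    """Full configuration of a network simulation.

    Times are in ms, conductances in nS, probabilities dimensionless.
    Defaults correspond to the reference mixed network: N = 1000 neurons,
    80% excitatory, within-population connection probabilities
    p_e = 0.05 / p_i = 0.2, cross-population p_ei = p_ie = 0.05, one
    autapse on 25% of each population, delays d_exc = 1.5 ms /
    d_inh = 0.8 ms, RK4 step 0.01 ms, and a 10-20 s analysis window.
    Conductances default to zero (uncoupled) and are the experiment
    variables.
    """

    N: int = 1000
    P_exc: float = 0.8
    # connection probabilities
    p_e: float = 0.05
    p_i: float = 0.2
    p_ei: float = 0.05
    p_ie: float = 0.05
    p_e_aut: float = 0.25
    p_i_aut: float = 0.25
    # conductances (nS)
    g_e: float = 0.0
    g_i: float = 0.0
    g_ei: float = 0.0
    g_ie: float = 0.0
    g_e_aut: float = 0.0
    g_i_aut: float = 0.0
    # delays (ms)
    d_exc: float = 1.5
    d_inh: float = 0.8
    # timing (ms)
    T_total: float = 20_000.0
    t_ini: float = 10_000.0
    t_fin: float = 20_000.0
    dt: float = 0.01
    seed: int = 0
    # shared neuron constants (a, b below override per population)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    # per-population adaptation: excitatory a drawn uniformly per neuron,
    # inhibitory adaptation absent
    a_exc_range: tuple[float, float] = (1.9, 2.1)
    b_exc: float = 70.0
    a_inh: float = 0.0
    b_inh: float = 0.0
    # synaptic reversal potentials (mV)
    V_rev_exc: float = 0.0
    V_rev_inh: float = -80.0
    # initial-condition ranges
    V0_range: tuple[float, float] = (-70.0, -50.0)
    w0_exc_range: tuple[float, float] = (0.0, 300.0)
    w0_inh_range: tuple[float, float] = (0.0, 80.0)
    # recording grid for the mean synaptic current (ms)
    record_current_every: float = 0.1

    @property
    def P_inh(self) -> float:
        return 1.0 - self.P_exc

    @property
    def n_exc(self) -> int:
        return int(round(self.P_exc * self.N))

    @property
    def n_inh(self) -> int:
        return self.N - self.n_exc

    def validate(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        probs = {
            "P_exc": self.P_exc,
            "p_e": self.p_e,
            "p_i": self.p_i,
            "p_ei": self.p_ei,
            "p_ie": self.p_ie,
            "p_e_aut": self.p_e_aut,
            "p_i_aut": self.p_i_aut,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in CONDUCTANCE_RANGES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.t_ini < self.t_fin <= self.T_total):
            raise ValueError("require t_ini < t_fin <= T_total")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d_exc < 0 or self.d_inh < 0:
            raise ValueError("delays must be non-negative")
        if self.record_current_every <= 0:
            raise ValueError("record_current_every must be positive")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["neuron"] = asdict(self.neuron)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "neuron" in d and isinstance(d["neuron"], dict):
            d["neuron"] = NeuronParams(**d["neuron"])
        for k in ("a_exc_range", "V0_range", "w0_exc_range", "w0_inh_range"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def replace(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)

    def content_hash(self) -> str:
        """Short stable hash of the configuration, for output headers."""
        items = sorted(self.to_dict().items())
        payload = repr(items).encode()
        return hashlib.md5(payload).hexdigest()[:8]


def build_populations(N: int, P_exc: float) -> np.ndarray:
    """Label the first ``round(P_exc * N)`` neurons excitatory.

    Returns a boolean array ``is_exc`` of length N.  Neurons are indexed
    0..N-1 internally (1..N in files and documentation).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0.0 <= P_exc <= 1.0:
        raise ValueError("P_exc must lie in [0, 1]")
    n_exc = int(round(P_exc * N))
    is_exc = np.zeros(N, dtype=bool)
    is_exc[:n_exc] = True
    return is_exc


def sample_random_edges(
    pre_ids: Sequence[int],
    post_ids: Sequence[int],
    p: float,
    rng: np.random.Generator,
    allow_self: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(p) sample of directed edges over ``pre x post``.

    Each ordered pair is included independently with probability ``p``;
    pairs with identical endpoints are excluded unless ``allow_self``.
    Returns (pre, post) index arrays.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    pre = np.asarray(pre_ids, dtype=np.int64)
    post = np.asarray(post_ids, dtype=np.int64)
    if pre.size == 0 or post.size == 0 or p == 0.0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    mask = rng.random((pre.size, post.size)) < p
    if not allow_self:
        mask &= pre[:, None] != post[None, :]
    ii, jj = np.nonzero(mask)
    return pre[ii], post[jj]


def assign_autapses(
    population: Sequence[int], p_aut: float, rng: np.random.Generator
) -> np.ndarray:
    """Choose exactly ``round(p_aut * |population|)`` autaptic neurons.

    The autapse probability is a count ratio (number of autapses over
    population size), so the count is deterministic; only the identity of
    the flagged neurons is random.
    """
    if not 0.0 <= p_aut <= 1.0:
        raise ValueError("p_aut must lie in [0, 1]")
    pop = np.asarray(population, dtype=np.int64)
    k = int(round(p_aut * pop.size))
    if k == 0:
        return np.empty(0, np.int64)
    chosen = rng.choice(pop, size=k, replace=False)
    return np.sort(chosen)


@dataclass
class NetworkGraph:
    """Directed network with labelled edge classes and autapse flags.

    Attributes
    ----------
    n : int
        Number of neurons.
    is_exc : (n,) bool
        Population label per neuron; excitatory neurons occupy the
        leading indices.
    pre, post : (E,) int64
        Edge endpoint indices (0-based; presynaptic -> postsynaptic).
    cls : (E,) int8
        Edge-class codes indexing :data:`EDGE_CLASSES`.
    weights : dict
        Edge class -> conductance (nS), a snapshot of the configuration
        the graph was built from.  Simulations resolve weights from the
        *current* configuration so a sweep can reuse one topology.
    autaptic : (n,) bool
        Whether the neuron has a self-loop.
    """

    n: int
    is_exc: np.ndarray
    pre: np.ndarray
    post: np.ndarray
    cls: np.ndarray
    weights: dict
    autaptic: np.ndarray

    # -- basic views --------------------------------------------------
    @property
    def n_exc(self) -> int:
        return int(self.is_exc.sum())

    @property
    def n_inh(self) -> int:
        return self.n - self.n_exc

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)

    def class_names(self) -> np.ndarray:
        return np.asarray(EDGE_CLASSES, dtype=object)[self.cls]

    def class_counts(self) -> dict:
        names = self.class_names()
        return {c: int((names == c).sum()) for c in EDGE_CLASSES}

    def edge_weights(self, weights: dict | None = None) -> np.ndarray:
        """Per-edge conductance array under a class->weight map."""
        w = self.weights if weights is None else weights
        lut = np.array([w.get(c, 0.0) for c in EDGE_CLASSES], dtype=np.float64)
        return lut[self.cls]

    def adjacency(self, kind: str = "exc") -> np.ndarray:
        """Binary adjacency matrix M[j, k] = 1 for an edge k -> j whose
        presynaptic neuron belongs to the requested population."""
        if kind not in ("exc", "inh"):
            raise ValueError("kind must be 'exc' or 'inh'")
        sel = self.is_exc[self.pre] if kind == "exc" else ~self.is_exc[self.pre]
        M = np.zeros((self.n, self.n), dtype=np.int8)
        M[self.post[sel], self.pre[sel]] = 1
        return M

    def presyn_csr(self, weights: dict | None = None):
        """Per-target CSR arrays split by presynaptic population.

        Returns ``(eptr, eidx, ewt, iptr, iidx, iwt)`` where for target j
        the excitatory inputs are ``eidx[eptr[j]:eptr[j+1]]`` with
        conductances ``ewt[...]``, and analogously for inhibitory inputs.
        """
        w_edge = self.edge_weights(weights)
        out = []
        for sel in (self.is_exc[self.pre], ~self.is_exc[self.pre]):
            pre = self.pre[sel]
            post = self.post[sel]
            wts = w_edge[sel]
            order = np.argsort(post, kind="stable")
            counts = np.bincount(post, minlength=self.n)
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            out.extend([indptr, pre[order].astype(np.int64), wts[order].astype(np.float64)])
        return tuple(out)

    def empirical_probabilities(self) -> dict:
        """Recovered connection probabilities N_class / n_eligible_pairs."""
        counts = self.class_counts()
        ne, ni = self.n_exc, self.n_inh
        denom = {
            "ee": ne * (ne - 1),
            "ii": ni * (ni - 1),
            "ei": ne * ni,
            "ie": ne * ni,
            "e_aut": ne,
            "i_aut": ni,
        }
        return {c: counts[c] / denom[c] if denom[c] > 0 else np.nan for c in EDGE_CLASSES}

    # -- text I/O -----------------------------------------------------
    def save(self, path) -> None:
        """Write a tab-separated edge list (1-based neuron ids)."""
        names = self.class_names()
        w_edge = self.edge_weights()
        with open(path, "w") as fh:
            fh.write("# aeifnet edge list v1\n")
            fh.write(f"# N: {self.n}\n")
            fh.write(f"# n_exc: {self.n_exc}\n")
            aut = ",".join(str(i + 1) for i in np.nonzero(self.autaptic)[0])
            fh.write(f"# autaptic: {aut}\n")
            fh.write("pre_id\tpost_id\tclass\tweight_nS\n")
            for k in range(self.n_edges):
                fh.write(f"{self.pre[k] + 1}\t{self.post[k] + 1}\t{names[k]}\t{w_edge[k]:g}\n")

    @classmethod
    def load(cls, path) -> "NetworkGraph":
        meta = {}
        pre, post, names, wts = [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if ":" in line:
                        key, _, val = line[1:].partition(":")
                        meta[key.strip()] = val.strip()
                    continue
                if line.startswith("pre_id") or not line:
                    continue
                a, b, c, w = line.split("\t")
                pre.append(int(a) - 1)
                post.append(int(b) - 1)
                names.append(c)
                wts.append(float(w))
        n = int(meta["N"])
        n_exc = int(meta["n_exc"])
        is_exc = np.zeros(n, dtype=bool)
        is_exc[:n_exc] = True
        autaptic = np.zeros(n, dtype=bool)
        if meta.get("autaptic"):
            ids = [int(s) - 1 for s in meta["autaptic"].split(",") if s]
            autaptic[ids] = True
        cls_codes = np.array([_CODE[c] for c in names], dtype=np.int8)
        weights = {}
        for c, w in zip(names, wts):
            weights.setdefault(c, w)
        return cls(
            n=n,
            is_exc=is_exc,
            pre=np.asarray(pre, np.int64),
            post=np.asarray(post, np.int64),
            cls=cls_codes,
            weights=weights,
            autaptic=autaptic,
        )


def assemble_network(
    config: NetworkConfig, rng: np.random.Generator | None = None
) -> NetworkGraph:
    """Sample the random network defined by ``config``.

    Wiring uses the ``graph`` RNG stream and autapse placement the
    ``autapse`` stream of ``config.seed`` (unless an explicit generator
    is given, in which case it drives both).  Cross-population
    probabilities are ignored (with a warning) when one population is
    absent, since they are undefined in that case.
    """
    config.validate()
    if rng is None:
        rng_graph = stream_rng(config.seed, STREAM_GRAPH)
        rng_aut = stream_rng(config.seed, STREAM_AUTAPSE)
    else:
        rng_graph = rng_aut = rng

    is_exc = build_populations(config.N, config.P_exc)
    exc_ids = np.nonzero(is_exc)[0]
    inh_ids = np.nonzero(~is_exc)[0]

    if exc_ids.size == 0 and (config.p_ei > 0 or config.p_ie > 0 or config.p_e > 0):
        logger.warning("no excitatory neurons: p_e, p_ei, p_ie ignored")
    if inh_ids.size == 0 and (config.p_ei > 0 or config.p_ie > 0 or config.p_i > 0):
        logger.warning("no inhibitory neurons: p_i, p_ei, p_ie ignored")

    pres, posts, codes = [], [], []

    def add(pre, post, cname):
        pres.append(pre)
        posts.append(post)
        codes.append(np.full(pre.size, _CODE[cname], dtype=np.int8))

    add(*sample_random_edges(exc_ids, exc_ids, config.p_e, rng_graph), "ee")
    add(*sample_random_edges(exc_ids, inh_ids, config.p_ei, rng_graph), "ei")
    add(*sample_random_edges(inh_ids, inh_ids, config.p_i, rng_graph), "ii")
    add(*sample_random_edges(inh_ids, exc_ids, config.p_ie, rng_graph), "ie")

    autaptic = np.zeros(config.N, dtype=bool)
    aut_e = assign_autapses(exc_ids, config.p_e_aut, rng_aut)
    aut_i = assign_autapses(inh_ids, config.p_i_aut, rng_aut)
    autaptic[aut_e] = True
    autaptic[aut_i] = True
    add(aut_e, aut_e.copy(), "e_aut")
    add(aut_i, aut_i.copy(), "i_aut")

    weights = {c: getattr(config, CLASS_TO_CONDUCTANCE[c]) for c in EDGE_CLASSES}
    return NetworkGraph(
        n=config.N,
        is_exc=is_exc,
        pre=np.concatenate(pres),
        post=np.concatenate(posts),
        cls=np.concatenate(codes),
        weights=weights,
        autaptic=autaptic,
    )
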