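"""Synthetic networks, signatures, expression, and survival with planted truth.

Every stage of the analysis is testable against a known answer: a sparse
directed acyclic network carries a planted high-out-degree driver whose
two-layer downstream cone hosts about half of each of two resistance-style
signatures (so the raw signature overlap stays small while the network
neighborhoods converge); expression plants positively and negatively
driver-correlated genes; survival times are exponential with group- and
arm-dependent hazards (treatment benefit confined to the driver-low group).

All generators are bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .net_core import GeneNetwork, GeneSignature, neighborhood
from .stratify import SampleStrata

# generator defaults: the study conditions every planted-truth check runs at
N_GENES = 2_000
ATTACH = 2
DRIVER_OUT = 40
DEPTH = 2
ATTACH_SMOOTHING = 5.0
SIZE_A = 359
SIZE_B = 223
FRAC_IN_CONE = 0.5
N_SAMPLES = 500
BETA = 0.6
NOISE_SD = 1.0
N_POS = 249
N_NEG = 124
FRAC_HIGH = 1.0 / 3.0
CENSOR_RATE = 0.02
MAX_FOLLOW_UP = 60.0  # months

TRANSCRIPTOME_UNIVERSE = 24_700


def _gene(i: int) -> str:
    return f"G{i:05d}"


@dataclass
class SyntheticTruth:
    """Planted ground truth accumulated across the generators."""

    seed: int
    driver: str = ""
    cone: frozenset[str] = frozenset()
    sig_a: frozenset[str] = frozenset()
    sig_b: frozenset[str] = frozenset()
    pos_genes: frozenset[str] = frozenset()
    neg_genes: frozenset[str] = frozenset()
    sample_groups: pd.Series | None = None
    hazards: dict | None = None
    params: dict = field(default_factory=dict)

    def write_manifest(self, path: str | Path) -> None:
        doc = {"seed": self.seed, "driver": self.driver,
               "cone_size": len(self.cone),
               "params": {k: (float(v) if isinstance(v, (int, float)) else v)
                          for k, v in self.params.items()}}
        if self.hazards:
            doc["hazards"] = {f"{g}|{a}": float(r)
                              for (g, a), r in sorted(self.hazards.items())}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def generate_network(
    n_genes: int = N_GENES,
    attach: int = ATTACH,
    driver_out: int = DRIVER_OUT,
    depth: int = DEPTH,
    seed: int = 0,
    smoothing: float = ATTACH_SMOOTHING,
) -> tuple[GeneNetwork, SyntheticTruth]:
    """Sparse directed acyclic network with a planted hub driver.

    Nodes are indexed 0..n-1 and edges only run from earlier to later
    indices, so the graph is acyclic by construction (a Bayesian-network
    style DAG).  Node 0 is the driver with ``driver_out`` direct targets,
    each rooting a chain of ``depth`` planted nodes.  On top, every node
    receives ``attach`` backbone in-edges from earlier nodes sampled with
    probability proportional to (backbone out-degree + smoothing) — a
    smoothed preferential attachment that yields realistic hubby sparse
    graphs without letting any cone blanket the network.
    """
    if n_genes < driver_out * depth + 10:
        raise ValueError(
            f"n_genes must be >= driver_out*depth + 10 = {driver_out * depth + 10}")
    if attach < 1 or driver_out < 1 or depth < 1:
        raise ValueError("attach, driver_out and depth must be positive")
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = []
    # planted driver structure: driver -> roots, root chains through levels
    for r in range(1, driver_out + 1):
        edges.append((0, r))
        prev = r
        for level in range(1, depth):
            child = level * driver_out + r
            edges.append((prev, child))
            prev = child
    planted = {(u, v) for u, v in edges}
    backbone_outdeg = np.zeros(n_genes)
    for j in range(1, n_genes):
        w = backbone_outdeg[:j] + smoothing
        srcs = rng.choice(j, size=min(attach, j), replace=False, p=w / w.sum())
        for s in srcs:
            s = int(s)
            if (s, j) not in planted:
                edges.append((s, j))
                backbone_outdeg[s] += 1
    net = GeneNetwork(edges=((_gene(u), _gene(v)) for u, v in edges),
                      nodes=(_gene(i) for i in range(n_genes)),
                      name=f"synthetic-dag-seed{seed}")
    driver = _gene(0)
    cone = frozenset(neighborhood(net, {driver}, depth, "downstream") - {driver})
    truth = SyntheticTruth(seed=seed, driver=driver, cone=cone,
                           params={"n_genes": n_genes, "attach": attach,
                                   "driver_out": driver_out, "depth": depth,
                                   "smoothing": smoothing})
    return net, truth


def generate_signatures(
    truth: SyntheticTruth,
    size_a: int = SIZE_A,
    size_b: int = SIZE_B,
    frac_in_cone: float = FRAC_IN_CONE,
    seed: int | None = None,
) -> tuple[GeneSignature, GeneSignature]:
    """Two partially cone-resident signatures with small raw overlap.

    Each signature draws ``frac_in_cone`` of its genes from the driver's
    downstream cone — disjointly between the signatures where the cone is
    large enough, so the direct overlap stays small — and the remainder
    uniformly from non-cone genes (driver excluded).
    """
    if not 0.0 <= frac_in_cone <= 1.0:
        raise ValueError("frac_in_cone must be in [0, 1]")
    n_genes = int(truth.params["n_genes"])
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cone = sorted(truth.cone)
    non_cone = sorted(set(_gene(i) for i in range(n_genes))
                      - truth.cone - {truth.driver})
    n_a_cone = round(size_a * frac_in_cone)
    n_b_cone = round(size_b * frac_in_cone)
    if size_a - n_a_cone > len(non_cone) or size_b - n_b_cone > len(non_cone):
        raise ValueError("not enough non-cone genes for the requested sizes")
    if min(n_a_cone, n_b_cone) > len(cone):
        raise ValueError("cone too small for the requested in-cone fractions")
    perm = rng.permutation(len(cone))
    a_cone = [cone[i] for i in perm[:n_a_cone]]
    if len(cone) >= n_a_cone + n_b_cone:
        b_cone = [cone[i] for i in perm[n_a_cone:n_a_cone + n_b_cone]]
    else:  # cone exhausted: reuse the earliest of A's cone draw
        short = n_a_cone + n_b_cone - len(cone)
        b_cone = [cone[i] for i in perm[n_a_cone:]] + a_cone[:short]
    a_rest = rng.choice(non_cone, size=size_a - n_a_cone, replace=False)
    b_rest = rng.choice(non_cone, size=size_b - n_b_cone, replace=False)
    sig_a = GeneSignature(name="EPres-like", source="synthetic planted",
                          genes=frozenset(a_cone) | frozenset(a_rest))
    sig_b = GeneSignature(name="Cisplatinres-like", source="synthetic planted",
                          genes=frozenset(b_cone) | frozenset(b_rest))
    truth.sig_a, truth.sig_b = sig_a.genes, sig_b.genes
    truth.params.update({"size_a": size_a, "size_b": size_b,
                         "frac_in_cone": frac_in_cone})
    return sig_a, sig_b


def generate_expression(
    truth: SyntheticTruth,
    n_samples: int = N_SAMPLES,
    beta: float = BETA,
    noise_sd: float = NOISE_SD,
    n_pos: int = N_POS,
    n_neg: int = N_NEG,
    seed: int | None = None,
    group_delta: float = 0.0,
    frac_high: float = FRAC_HIGH,
):
    """Expression matrix with planted driver-correlated genes.

    The driver row is standard normal across samples; ``n_pos`` planted
    genes follow +beta * driver + N(0, noise_sd^2), ``n_neg`` follow
    -beta * driver + noise, and every remaining gene is pure noise.  With
    ``group_delta`` > 0, samples are first split into planted "high"
    (fraction ``frac_high``) and "low" groups and the driver mean is
    shifted by +/- group_delta/2, planting a two-population cohort for
    stratification checks; the split is recorded in the truth.
    """
    from .assoc import ExpressionMatrix

    if beta < 0 or noise_sd <= 0:
        raise ValueError("beta must be >= 0 and noise_sd > 0")
    n_genes = int(truth.params["n_genes"])
    if n_pos + n_neg > n_genes - 1:
        raise ValueError("n_pos + n_neg exceeds available non-driver genes")
    rng = np.random.default_rng((truth.seed if seed is None else seed) + 1_000_003)
    genes = [_gene(i) for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]

    if group_delta > 0.0:
        n_high = round(frac_high * n_samples)
        group_idx = rng.permutation(n_samples)
        groups = np.array(["low"] * n_samples, dtype=object)
        groups[group_idx[:n_high]] = "high"
        shift = np.where(groups == "high", group_delta / 2.0, -group_delta / 2.0)
    else:
        groups = None
        shift = 0.0
    driver_row = shift + rng.standard_normal(n_samples)

    others = [g for g in genes if g != truth.driver]
    pick = rng.permutation(len(others))
    pos = [others[i] for i in pick[:n_pos]]
    neg = [others[i] for i in pick[n_pos:n_pos + n_neg]]

    mat = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    index = {g: i for i, g in enumerate(genes)}
    mat[index[truth.driver]] = driver_row
    for g in pos:
        mat[index[g]] += beta * driver_row
    for g in neg:
        mat[index[g]] -= beta * driver_row

    truth.pos_genes, truth.neg_genes = frozenset(pos), frozenset(neg)
    if groups is not None:
        truth.sample_groups = pd.Series(groups, index=samples, name="group")
    truth.params.update({"n_samples": n_samples, "beta": beta,
                         "noise_sd": noise_sd, "n_pos": n_pos, "n_neg": n_neg,
                         "group_delta": group_delta})
    return ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=samples))


def default_hazards(
    base_rate: float = 0.10,
    treated_hr_low: float = 0.5,
    treated_hr_high: float = 1.0,
) -> dict[tuple[str, str], float]:
    """Exponential hazards (events/month) with treatment benefit only in the low group."""
    return {
        ("low", "untreated"): base_rate,
        ("low", "treated"): base_rate * treated_hr_low,
        ("high", "untreated"): base_rate,
        ("high", "treated"): base_rate * treated_hr_high,
    }


def generate_survival(
    strata: SampleStrata | pd.Series,
    arms: pd.Series | None = None,
    hazards: Mapping[tuple[str, str], float] | None = None,
    censor_rate: float = CENSOR_RATE,
    max_follow_up: float = MAX_FOLLOW_UP,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival records per sample with group x arm hazards.

    Event times are exponential with the hazard assigned to the sample's
    (group, arm); censoring is an independent exponential time at
    ``censor_rate`` plus administrative censoring at ``max_follow_up``.
    ``arms`` defaults to a seeded 50/50 treated/untreated split.
    """
    groups = strata.groups if isinstance(strata, SampleStrata) else strata
    samples = list(groups.index.astype(str))
    rng = np.random.default_rng(seed + 2_000_003)
    if arms is None:
        half = np.array(["treated", "untreated"])[
            rng.integers(0, 2, size=len(samples))]
        arms = pd.Series(half, index=samples, name="arm")
    if hazards is None:
        hazards = default_hazards()
    rates = np.array([hazards[(groups[s], arms[s])] for s in samples])
    if np.any(rates <= 0):
        raise ValueError("hazard rates must be positive")
    if censor_rate < 0 or max_follow_up <= 0:
        raise ValueError("censor_rate must be >= 0 and max_follow_up > 0")
    ev = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        cens = rng.exponential(1.0 / censor_rate, size=len(samples))
    else:
        cens = np.full(len(samples), np.inf)
    cens = np.minimum(cens, max_follow_up)
    time = np.minimum(ev, cens)
    event = (ev <= cens).astype(int)
    return pd.DataFrame({
        "sample": samples,
        "time": time,
        "event": event,
        "arm": [arms[s] for s in samples],
        "group": [groups[s] for s in samples],
    })


def published_scale_signatures(
    seed: int = 0,
    universe: int = TRANSCRIPTOME_UNIVERSE,
    size_a: int = SIZE_A,
    size_b: int = SIZE_B,
    overlap: int = 9,
) -> tuple[GeneSignature, GeneSignature, int]:
    """Synthetic stand-in for the published supplementary resistance lists.

    Draws two gene lists of the published sizes (359 and 223) sharing
    exactly ``overlap`` genes (9) from a whole-transcriptome-scale universe
    of ``universe`` genes, so list bookkeeping and the worked Fisher
    example can be exercised without the original supplementary file.
    Returns (sig_a, sig_b, universe size).
    """
    if overlap > min(size_a, size_b) or size_a + size_b - overlap > universe:
        raise ValueError("infeasible margins")
    rng = np.random.default_rng(seed)
    ids = rng.choice(universe, size=size_a + size_b - overlap, replace=False)
    shared = ids[:overlap]
    a_only = ids[overlap:size_a]
    b_only = ids[size_a:]
    sig_a = GeneSignature(
        name="EP-res", source="synthetic stand-in for published PDX list",
        genes=frozenset(_gene(i) for i in np.concatenate([shared, a_only])))
    sig_b = GeneSignature(
        name="Cisplatin-res", source="synthetic stand-in for published GEMM list",
        genes=frozenset(_gene(i) for i in np.concatenate([shared, b_only])))
    return sig_a, sig_b, universe
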