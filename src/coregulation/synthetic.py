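"""Synthetic worlds with known, planted co-regulation structure.

The generator emulates the *statistical* structure of per-gene
translational-parameter data joined to an interactome — not the mechanism
that produces such parameters. Its model:

* Parameter marginals are log-normal: every translational quantity is
  positive and heavy-tailed (genome-wide production rates span several
  orders of magnitude), and log-normality yields closed-form targets for
  fold-change statistics.
* Complexes are groups whose members share, for each *planted* parameter,
  a latent per-complex factor: for protein *i* of complex *c*,

  ``log p_i = mu_p + sigma_p * (sqrt(rho_c)*Z_c + sqrt(1-rho_c)*eps_i)``

  giving a within-complex latent Pearson correlation ``rho_c`` on the log
  scale (hence a within-pair Spearman of ``(6/pi)*arcsin(rho_c/2)``).
* Binary edges connect members of *different* complexes, at most one per
  protein; a per-edge factor with weight ``rho_b`` is blended in the same
  way, so binary partners correlate at ``rho_b`` while within-complex
  correlation stays ``rho_c`` (requires ``rho_c + rho_b <= 1``).
* Operons are disjoint groups sharing a polycistronic transcript: all
  members copy a single drawn transcript abundance ``x`` and lifetime
  ``m`` verbatim; other parameters are independent.
* Party hubs are extra proteins embedded in one large complex (high
  degree, co-regulated with all partners at ``rho_c``); date hubs are
  members of several complexes with an independent latent (high degree
  spread across modules, uncorrelated with partners).
* Internal identities of the parameter table hold exactly: ``b = m/I``,
  ``E = e*L`` and ``w = g*L/100``, so consistency checks downstream see a
  coherent table.

Complex and operon sizes follow a truncated power law, approximating the
scale-free character of biological networks; the exponent is a knob, not
a claim. Everything is deterministic given the config seed, and
:func:`write_world` emits the exact on-disk formats the readers consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .interactions import GroupTable, InteractionSet, Pair
from .params import ParamsTable, write_params_table

__all__ = ["WorldConfig", "SyntheticWorld", "simulate_world", "write_world", "load_world"]

#: Base parameters drawn directly; the rest are derived identities.
_BASE_PARAMS = ("L", "x", "g", "m", "I", "e", "A")

_DEFAULT_LOG_MEANS = {
    "L": math.log(400.0),   # codons
    "x": math.log(5.0),     # transcripts per cell
    "g": math.log(0.8),     # ribosomes per 100 codons
    "m": math.log(1200.0),  # seconds
    "I": math.log(300.0),   # seconds
    "e": math.log(0.06),    # seconds per codon
    "A": math.log(2000.0),  # molecules per cell
}

_DEFAULT_LOG_SDS = {
    "L": 0.6, "x": 1.2, "g": 0.5, "m": 0.7, "I": 0.8, "e": 0.3, "A": 1.5,
}


@dataclass(frozen=True)
class WorldConfig:
    """Study-condition knobs of the synthetic world.

    The default sizes emulate a yeast-scale analysis: roughly six thousand
    co-complex pairs, a binary network of a thousand direct interactions,
    several hundred operons, and 108 party / 91 date hubs whose edges sit
    inside single modules and across at least three modules respectively.

    ``rho_complex`` / ``rho_binary`` are latent Pearson correlations of
    log-parameters planted within complexes and binary pairs; the latent
    blend requires ``0 <= rho_binary <= rho_complex`` and
    ``rho_complex + rho_binary <= 1``.
    """

    seed: int = 0
    n_complexes: int = 600
    complex_size_min: int = 3
    complex_size_max: int = 12
    complex_size_exponent: float = 2.5
    rho_complex: float = 0.6
    rho_binary: float = 0.3
    n_binary_edges: int = 1000
    n_operons: int = 400
    operon_size_min: int = 1
    operon_size_max: int = 8
    operon_size_exponent: float = 2.0
    n_free_proteins: int = 600
    n_party_hubs: int = 108
    n_date_hubs: int = 91
    date_hub_complexes: int = 3
    planted_parameters: tuple[str, ...] = ("x", "I", "A", "e")
    log_means: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOG_MEANS))
    log_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOG_SDS))
    abundance_coverage: float = 0.7
    missing_m_b_fraction: float = 0.25

    def validate(self) -> None:
        if not (0.0 <= self.rho_binary <= self.rho_complex <= 1.0):
            raise ValueError(
                f"need 0 <= rho_binary ({self.rho_binary}) <= rho_complex "
                f"({self.rho_complex}) <= 1"
            )
        if self.n_binary_edges > 0 and self.rho_complex + self.rho_binary > 1.0:
            raise ValueError(
                "rho_complex + rho_binary must not exceed 1 for the latent blend"
            )
        for name in ("n_complexes", "n_operons", "n_free_proteins",
                     "n_party_hubs", "n_date_hubs", "n_binary_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for lo, hi, what in (
            (self.complex_size_min, self.complex_size_max, "complex"),
            (self.operon_size_min, self.operon_size_max, "operon"),
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {what} size range [{lo}, {hi}]")
        if self.n_date_hubs > 0 and self.date_hub_complexes > max(self.n_complexes, 1):
            raise ValueError("date_hub_complexes exceeds the number of complexes")
        unknown = set(self.planted_parameters) - set(_BASE_PARAMS)
        if unknown:
            raise ValueError(
                f"planted parameters must be base parameters {_BASE_PARAMS}; "
                f"got {sorted(unknown)} (derived symbols inherit structure automatically)"
            )
        if not (0.0 <= self.abundance_coverage <= 1.0):
            raise ValueError("abundance_coverage must lie in [0, 1]")
        if not (0.0 <= self.missing_m_b_fraction <= 1.0):
            raise ValueError("missing_m_b_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticWorld:
    """A complete ground-truth bundle emitted by :func:`simulate_world`."""

    config: WorldConfig
    params: ParamsTable
    abundance: pd.DataFrame  # columns gene_id, A
    complexes: GroupTable
    operons: GroupTable
    binary: InteractionSet
    hubs: dict[str, tuple[str, ...]]  # keys "party", "date"
    ground_truth: dict

    def analysis_table(self) -> ParamsTable:
        """Parameter table with A merged and B, R derived — analysis-ready."""
        return (
            self.params.with_abundance(self.abundance)
            .with_total_production()
            .with_production_rate()
        )


def _power_law_sizes(rng, n: int, lo: int, hi: int, exponent: float) -> np.ndarray:
    ks = np.arange(lo, hi + 1)
    if len(ks) == 1:
        return np.full(n, lo)
    w = ks.astype(float) ** (-exponent)
    w /= w.sum()
    return rng.choice(ks, size=n, p=w)


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a synthetic world; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counter = [0]

    def new_ids(prefix: str, k: int) -> list[str]:
        out = [f"{prefix}{counter[0] + i:06d}" for i in range(k)]
        counter[0] += k
        return out

    # --- structure ---------------------------------------------------------
    complex_sizes = _power_law_sizes(
        rng, config.n_complexes, config.complex_size_min,
        config.complex_size_max, config.complex_size_exponent,
    )
    complexes: dict[str, list[str]] = {}
    for i, k in enumerate(complex_sizes):
        complexes[f"CPX{i:04d}"] = new_ids("G", int(k))
    complex_members = [m for ms in complexes.values() for m in ms]
    complex_of = {m: cid for cid, ms in complexes.items() for m in ms}

    operon_sizes = _power_law_sizes(
        rng, config.n_operons, config.operon_size_min,
        config.operon_size_max, config.operon_size_exponent,
    ) if config.n_operons else np.array([], dtype=int)
    operons: dict[str, list[str]] = {}
    for i, k in enumerate(operon_sizes):
        operons[f"OPR{i:04d}"] = new_ids("G", int(k))
    operon_members = [m for ms in operons.values() for m in ms]

    free_proteins = new_ids("G", config.n_free_proteins)

    # party hubs join one large complex each (round-robin over the largest)
    by_size = sorted(complexes, key=lambda c: (-len(complexes[c]), c))
    party_hubs = new_ids("G", config.n_party_hubs)
    if party_hubs and not by_size:
        raise ValueError("party hubs require at least one complex")
    for i, hub in enumerate(party_hubs):
        cid = by_size[i % len(by_size)]
        complexes[cid].append(hub)
        complex_of[hub] = cid  # single membership: co-regulated with the module

    # date hubs join several complexes; multi-membership means no single
    # module factor applies, so their latents stay independent noise
    date_hubs = new_ids("G", config.n_date_hubs)
    multi_membership: dict[str, list[str]] = {}
    if date_hubs and len(complexes) < config.date_hub_complexes:
        raise ValueError("not enough complexes to spread date hubs over")
    all_cids = sorted(complexes)
    for hub in date_hubs:
        picked = rng.choice(len(all_cids), size=config.date_hub_complexes, replace=False)
        homes = [all_cids[j] for j in sorted(picked)]
        for cid in homes:
            complexes[cid].append(hub)
        multi_membership[hub] = homes

    # binary edges: disjoint pairs of single-membership complex members from
    # different complexes
    binary_pairs: list[Pair] = []
    pair_of: dict[str, int] = {}
    pool = list(complex_members)
    perm = rng.permutation(len(pool))
    pool = [pool[i] for i in perm]
    while len(binary_pairs) < config.n_binary_edges and len(pool) >= 2:
        a = pool.pop()
        j = next(
            (k for k in range(len(pool) - 1, -1, -1)
             if complex_of[pool[k]] != complex_of[a]),
            None,
        )
        if j is None:
            continue
        b = pool.pop(j)
        pair_of[a] = pair_of[b] = len(binary_pairs)
        binary_pairs.append((a, b) if a < b else (b, a))
    if len(binary_pairs) < config.n_binary_edges:
        raise ValueError(
            f"infeasible config: only {len(binary_pairs)} cross-complex binary "
            f"edges possible, {config.n_binary_edges} requested"
        )

    proteins = complex_members + operon_members + free_proteins + party_hubs + date_hubs
    n = len(proteins)
    pos = {g: i for i, g in enumerate(proteins)}

    # --- latent parameter draws -------------------------------------------
    rho_c, rho_b = config.rho_complex, config.rho_binary
    sqrt_c, sqrt_b = math.sqrt(rho_c), math.sqrt(rho_b)
    single_member = np.zeros(n, dtype=bool)
    for g in complex_members + party_hubs:
        single_member[pos[g]] = True
    in_binary = np.zeros(n, dtype=bool)
    complex_idx = np.zeros(n, dtype=int)
    cid_order = {cid: i for i, cid in enumerate(sorted(complexes))}
    for g, cid in complex_of.items():
        complex_idx[pos[g]] = cid_order[cid]
    pair_idx = np.zeros(n, dtype=int)
    for g, k in pair_of.items():
        in_binary[pos[g]] = True
        pair_idx[pos[g]] = k

    log_values: dict[str, np.ndarray] = {}
    complex_factors: dict[str, dict[str, float]] = {}
    for p in _BASE_PARAMS:
        mu = config.log_means[p]
        sigma = config.log_sds[p]
        eps = rng.standard_normal(n)
        if p in config.planted_parameters:
            Z = rng.standard_normal(len(complexes))
            Y = rng.standard_normal(max(len(binary_pairs), 1))
            a = np.where(single_member, sqrt_c, 0.0)
            bb = np.where(in_binary, sqrt_b, 0.0)
            cc = np.sqrt(1.0 - a**2 - bb**2)
            latent = a * Z[complex_idx] + bb * Y[pair_idx] + cc * eps
            complex_factors[p] = {
                cid: float(Z[cid_order[cid]]) for cid in sorted(complexes)
            }
        else:
            latent = eps
        log_values[p] = mu + sigma * latent

    # operon members share the polycistronic transcript: one x and one m per
    # operon, copied verbatim (other parameters stay independent)
    for oid in sorted(operons):
        members = operons[oid]
        shared_x = config.log_means["x"] + config.log_sds["x"] * rng.standard_normal()
        shared_m = config.log_means["m"] + config.log_sds["m"] * rng.standard_normal()
        for g in members:
            log_values["x"][pos[g]] = shared_x
            log_values["m"][pos[g]] = shared_m

    L = np.maximum(1, np.round(np.exp(log_values["L"]))).astype(float)
    x = np.exp(log_values["x"])
    g_dens = np.exp(log_values["g"])
    m = np.exp(log_values["m"])
    I = np.exp(log_values["I"])
    e = np.exp(log_values["e"])
    A = np.exp(log_values["A"])
    b = m / I           # the steady-state identity, exact by construction
    E = e * L           # elongation time of the whole transcript
    w = g_dens * L / 100.0

    # partial coverage of m and b, jointly (they come from the same source)
    if config.missing_m_b_fraction > 0:
        k = int(round(config.missing_m_b_fraction * n))
        drop = rng.choice(n, size=k, replace=False)
        m = m.copy(); b = b.copy()
        m[drop] = np.nan
        b[drop] = np.nan

    frame = pd.DataFrame(
        {"L": L, "x": x, "g": g_dens, "w": w, "m": m, "I": I, "E": E, "e": e, "b": b},
        index=pd.Index(proteins, name="gene_id"),
    )
    params = ParamsTable(frame)

    k_ab = int(round(config.abundance_coverage * n))
    covered = rng.choice(n, size=k_ab, replace=False)
    covered_ids = sorted(proteins[i] for i in covered)
    abundance = pd.DataFrame(
        {"gene_id": covered_ids, "A": [A[pos[g]] for g in covered_ids]}
    )

    ground_truth = {
        "config": _config_to_jsonable(config),
        "planted_parameters": list(config.planted_parameters),
        "rho_complex": rho_c,
        "rho_binary": rho_b,
        "spearman_target_complex": 6.0 / math.pi * math.asin(rho_c / 2.0),
        "spearman_target_binary": 6.0 / math.pi * math.asin(rho_b / 2.0),
        "n_proteins": n,
        "complex_sizes": [int(s) for s in complex_sizes],
        "operon_sizes": [int(s) for s in operon_sizes],
        "date_hub_membership": {h: list(c) for h, c in multi_membership.items()},
        "complex_factors": complex_factors,
        "seed": config.seed,
    }

    return SyntheticWorld(
        config=config,
        params=params,
        abundance=abundance,
        complexes=GroupTable({cid: tuple(ms) for cid, ms in complexes.items()}),
        operons=GroupTable({oid: tuple(ms) for oid, ms in operons.items()}),
        binary=InteractionSet(
            label="binary", pairs=frozenset(binary_pairs),
            source_note=f"synthetic, seed={config.seed}",
        ),
        hubs={"party": tuple(party_hubs), "date": tuple(date_hubs)},
        ground_truth=ground_truth,
    )


def _config_to_jsonable(config: WorldConfig) -> dict:
    d = asdict(config)
    d["planted_parameters"] = list(config.planted_parameters)
    d["log_means"] = dict(config.log_means)
    d["log_sds"] = dict(config.log_sds)
    return d


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, str]:
    """Write a world in the formats the pipeline readers consume.

    Emits the parameter TSV, abundance table, binary edge list, complex and
    operon membership files, hub lists, and a ``ground_truth.json`` manifest
    recording the config (seed included) and planted structure. Output is
    byte-identical across runs with the same config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "params": directory / "params.tsv",
        "abundance": directory / "abundance.tsv",
        "binary": directory / "binary_edges.tsv",
        "complexes": directory / "complexes.tsv",
        "operons": directory / "operons.tsv",
        "party_hubs": directory / "hubs_party.txt",
        "date_hubs": directory / "hubs_date.txt",
        "ground_truth": directory / "ground_truth.json",
    }
    write_params_table(world.params, paths["params"])
    world.abundance.to_csv(paths["abundance"], sep="\t", index=False)
    world.binary.to_file(paths["binary"])
    world.complexes.to_file(paths["complexes"])
    world.operons.to_file(paths["operons"])
    for key in ("party_hubs", "date_hubs"):
        hubs = world.hubs["party" if key == "party_hubs" else "date"]
        with open(paths[key], "w") as fh:
            for h in hubs:
                fh.write(h + "\n")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(world.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def load_world(directory: str | Path) -> SyntheticWorld:
    """Read back a written world through the real pipeline readers."""
    from .interactions import read_edge_list, read_group_table
    from .params import read_params_table

    directory = Path(directory)
    with open(directory / "ground_truth.json") as fh:
        ground_truth = json.load(fh)
    cfg_dict = dict(ground_truth["config"])
    cfg_dict["planted_parameters"] = tuple(cfg_dict["planted_parameters"])
    config = WorldConfig(**cfg_dict)
    params = read_params_table(directory / "params.tsv")
    abundance = pd.read_csv(directory / "abundance.tsv", sep="\t", dtype={"gene_id": str})
    binary = read_edge_list(directory / "binary_edges.tsv", label="binary")
    complexes = read_group_table(directory / "complexes.tsv")
    operons = read_group_table(directory / "operons.tsv")
    hubs = {}
    for key, fname in (("party", "hubs_party.txt"), ("date", "hubs_date.txt")):
        with open(directory / fname) as fh:
            hubs[key] = tuple(line.strip() for line in fh if line.strip())
    return SyntheticWorld(
        config=config, params=params, abundance=abundance,
        complexes=complexes, operons=operons, binary=binary,
        hubs=hubs, ground_truth=ground_truth,
    )
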