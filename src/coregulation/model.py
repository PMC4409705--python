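"""Model/Results objects tying the statistics to data.

:class:`CoregulationModel` is built from a parameter table plus a labelled
collection of interaction sets (real networks, operons and controls), in
the style of a statsmodels model: construction validates and stores the
data, ``fit()`` estimates and returns a results object carrying the
estimates, their intervals and a ``summary()`` table.

Three fits are exposed:

* :meth:`CoregulationModel.fit` — the correlation survey: one Spearman
  correlation with CI per (interaction set, parameter).
* :meth:`CoregulationModel.fit_fold_change` — within-pair fold-change
  medians and log-fold-change standard deviations per set, with bootstrap
  CIs, plus bootstrap CIs for between-set differences.
* :meth:`CoregulationModel.fit_hubs` — the survey restricted to edges of
  two hub classes (party/date) with degree-matched random controls, and
  Zou intervals for the party-minus-date correlation difference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .interactions import InteractionSet, restrict_to_analyzable
from .nullmodels import SamplingConfig, hub_matched_controls, sample_random_pairs, shuffle_interactome
from .params import ParamsTable, SYMBOLS
from .stats import (
    BootstrapInterval,
    CorrelationEstimate,
    DifferenceEstimate,
    bootstrap_difference_ci,
    bootstrap_statistic_ci,
    correlation_difference_ci,
    fold_changes,
    log_fold_changes,
    pair_values,
    spearman_with_ci,
)

DEFAULT_PARAMETERS: tuple[str, ...] = SYMBOLS


def _spawn_seed(root_seed: int, *path: object) -> int:
    """Derive a stable child seed below 2**31 from a root seed and a path.

    Uses CRC32 of the path components, not ``hash()``, so derived seeds are
    identical across processes regardless of hash randomization.
    """
    key = tuple(zlib.crc32(repr(p).encode()) for p in path)
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


class CoregulationModel:
    """Co-regulation of translational parameters across interaction sets.

    Parameters
    ----------
    params
        Parameter table, ideally with ``R`` and ``B`` derived and ``A``
        merged (see :meth:`from_world` for the synthetic path).
    interaction_sets
        Mapping ``name -> InteractionSet``. Names are analysis labels
        (``co-complex``, ``binary``, ``operon``, ``random``, ``shuffled``);
        any name is accepted.
    parameters
        Symbols to analyze; defaults to the full canonical set.
    """

    def __init__(
        self,
        params: ParamsTable,
        interaction_sets: Mapping[str, InteractionSet],
        parameters: Iterable[str] = DEFAULT_PARAMETERS,
    ):
        self.params = params
        self.interaction_sets = dict(interaction_sets)
        self.parameters = tuple(parameters)
        for p in self.parameters:
            if p not in SYMBOLS:
                raise KeyError(f"unknown parameter symbol {p!r}")
        if not self.interaction_sets:
            raise ValueError("at least one interaction set is required")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_world(cls, world, parameters: Iterable[str] = DEFAULT_PARAMETERS,
                   include_operons: bool = True) -> "CoregulationModel":
        """Build a model from a synthetic world (real networks only).

        Controls are added separately with :meth:`add_controls` so their
        seeds stay explicit.
        """
        from .interactions import expand_group_pairs

        table = world.analysis_table()
        sets: dict[str, InteractionSet] = {
            "co-complex": expand_group_pairs(world.complexes, label="co-complex"),
            "binary": world.binary.relabel("binary"),
        }
        if include_operons and len(world.operons):
            operon_pairs = expand_group_pairs(world.operons, label="operon")
            if len(operon_pairs):
                sets["operon"] = operon_pairs
        return cls(table, sets, parameters)

    def add_controls(self, n_random: int = 3000, seed: int = 0,
                     shuffle_source: str = "co-complex") -> "CoregulationModel":
        """Attach the two negative controls; returns self for chaining.

        ``random`` draws ``n_random`` pairs from all genes of the parameter
        table, excluding every pair of every real set already attached;
        ``shuffled`` label-permutes the ``shuffle_source`` network. One
        random set is generated and reused across parameters, with its
        seed recorded in the set's provenance note.
        """
        real = [s for name, s in self.interaction_sets.items()
                if name not in ("random", "shuffled")]
        excluded = real[0].union(*real[1:], label="excluded") if real else InteractionSet("excluded", frozenset())
        universe = frozenset(self.params.genes)
        config = SamplingConfig(
            universe=universe, excluded=excluded,
            target_count=n_random, seed=_spawn_seed(seed, "random-pairs"),
        )
        self.interaction_sets["random"] = sample_random_pairs(config)
        if shuffle_source in self.interaction_sets:
            self.interaction_sets["shuffled"] = shuffle_interactome(
                self.interaction_sets[shuffle_source], seed=_spawn_seed(seed, "shuffle")
            )
        return self

    # -- fits ---------------------------------------------------------------
    def fit(self, seed: int = 0, ci_method: str = "bonett-wright",
            level: float = 0.95) -> "CoregulationResults":
        """Estimate the per-(set, parameter) Spearman correlations.

        Pair orientation is randomized with seeds derived from ``seed``;
        (set, parameter) cells with fewer than 4 analyzable pairs yield a
        row with ``n`` and no estimate.
        """
        rows = []
        estimates: dict[tuple[str, str], CorrelationEstimate] = {}
        for name in self.interaction_sets:
            edges = self.interaction_sets[name]
            for param in self.parameters:
                usable = restrict_to_analyzable(edges, self.params, param)
                n = len(usable)
                est = None
                if n >= 4:
                    pv = pair_values(
                        usable, self.params, param,
                        order_policy="randomized",
                        seed=_spawn_seed(seed, name, param),
                    )
                    if np.ptp(pv.first) > 0 and np.ptp(pv.second) > 0:
                        est = spearman_with_ci(pv, level=level, method=ci_method,
                                               seed=_spawn_seed(seed, name, param, "boot"))
                if est is not None:
                    estimates[(name, param)] = est
                rows.append({
                    "set": name, "parameter": param, "n": n,
                    "rho": est.rho if est else np.nan,
                    "ci_low": est.ci_low if est else np.nan,
                    "ci_high": est.ci_high if est else np.nan,
                    "level": level, "method": ci_method,
                })
        frame = pd.DataFrame(rows)
        return CoregulationResults(model=self, frame=frame, estimates=estimates,
                                   level=level, seed=seed)

    def fit_fold_change(self, parameter: str = "R", reps: int = 2000,
                        method: str = "normal", level: float = 0.95,
                        seed: int = 0) -> "FoldChangeResults":
        """Fold-change medians and log-fold-change sds per set, with CIs."""
        rows = []
        samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name in self.interaction_sets:
            usable = restrict_to_analyzable(self.interaction_sets[name], self.params, parameter)
            if len(usable) == 0:
                rows.append({"set": name, "n": 0})
                continue
            pv = pair_values(usable, self.params, parameter,
                             order_policy="randomized", seed=_spawn_seed(seed, name, "orient"))
            fc = fold_changes(pv)
            lfc = log_fold_changes(pv, base="e")
            samples[name] = (fc, lfc)
            med = bootstrap_statistic_ci(fc, "median", reps=reps, method=method,
                                         level=level, seed=_spawn_seed(seed, name, "median"))
            sd = bootstrap_statistic_ci(lfc, "sd", reps=reps, method=method,
                                        level=level, seed=_spawn_seed(seed, name, "sd"))
            rows.append({
                "set": name, "n": len(fc),
                "median_fc": med.estimate, "median_ci_low": med.ci_low,
                "median_ci_high": med.ci_high,
                "sd_log_fc": sd.estimate, "sd_ci_low": sd.ci_low,
                "sd_ci_high": sd.ci_high,
                "log_base": "e", "reps": reps, "method": method, "level": level,
            })
        frame = pd.DataFrame(rows)
        return FoldChangeResults(model=self, parameter=parameter, frame=frame,
                                 samples=samples, reps=reps, method=method,
                                 level=level, seed=seed)

    def fit_hubs(self, party: Iterable[str], date: Iterable[str],
                 networks: Iterable[str] = ("co-complex", "binary"),
                 parameters: Iterable[str] | None = None,
                 control_seed: int = 0, fit_seed: int = 0,
                 level: float = 0.95, ci_method: str = "bonett-wright") -> "HubResults":
        """Correlation survey for party- vs date-hub edges, with controls.

        For each hub class and each named network, the edges incident to a
        hub of that class are extracted and analyzed like any interaction
        set. Degree-matched random controls (one per class, matched on the
        first network in ``networks``) are generated per parameter-carrying
        hub and analyzed identically; the party-minus-date difference gets
        a Zou interval per (network, parameter) and for the controls.
        """
        party = sorted(set(party))
        date = sorted(set(date))
        parameters = tuple(parameters) if parameters is not None else self.parameters
        match_net = next(iter(networks))

        sub_models: dict[tuple[str, str], InteractionSet] = {}
        for net in networks:
            edges = self.interaction_sets[net]
            for cls_name, hubs in (("party", party), ("date", date)):
                hub_set = set(hubs)
                pairs = frozenset(p for p in edges.pairs if p[0] in hub_set or p[1] in hub_set)
                sub_models[(cls_name, net)] = InteractionSet(
                    label=f"{cls_name}/{net}", pairs=pairs,
                    source_note=f"hub edges of {len(hubs)} {cls_name} hubs",
                )
        for cls_name, hubs in (("party", party), ("date", date)):
            sub_models[(cls_name, "control")] = hub_matched_controls(
                hubs, self.interaction_sets[match_net], self.params,
                parameter="R" if "R" in parameters else parameters[0],
                seed=_spawn_seed(control_seed, cls_name, "hub-control"),
            )

        rows = []
        estimates: dict[tuple[str, str, str], CorrelationEstimate] = {}
        for (cls_name, net), edges in sub_models.items():
            for param in parameters:
                usable = restrict_to_analyzable(edges, self.params, param)
                n = len(usable)
                est = None
                if n >= 4:
                    pv = pair_values(usable, self.params, param, "randomized",
                                     seed=_spawn_seed(fit_seed, cls_name, net, param))
                    if np.ptp(pv.first) > 0 and np.ptp(pv.second) > 0:
                        est = spearman_with_ci(pv, level=level, method=ci_method)
                if est is not None:
                    estimates[(cls_name, net, param)] = est
                rows.append({
                    "hub_class": cls_name, "network": net, "parameter": param,
                    "n": n,
                    "rho": est.rho if est else np.nan,
                    "ci_low": est.ci_low if est else np.nan,
                    "ci_high": est.ci_high if est else np.nan,
                })

        diff_rows = []
        differences: dict[tuple[str, str], DifferenceEstimate] = {}
        nets = list(networks) + ["control"]
        for net in nets:
            for param in parameters:
                e_party = estimates.get(("party", net, param))
                e_date = estimates.get(("date", net, param))
                if e_party is None or e_date is None:
                    continue
                diff = correlation_difference_ci(e_party, e_date, level=level)
                differences[(net, param)] = diff
                diff_rows.append({
                    "network": net, "parameter": param,
                    "delta": diff.delta, "ci_low": diff.ci_low,
                    "ci_high": diff.ci_high, "n_party": diff.n1, "n_date": diff.n2,
                })
        return HubResults(
            model=self,
            correlations=pd.DataFrame(rows),
            difference_frame=pd.DataFrame(diff_rows),
            estimates=estimates,
            differences=differences,
            level=level,
        )


@dataclass
class CoregulationResults:
    """Results of the correlation survey.

    ``frame`` is tidy: one row per (set, parameter) with ``rho``,
    ``ci_low``, ``ci_high`` and ``n``.
    """

    model: CoregulationModel
    frame: pd.DataFrame
    estimates: dict[tuple[str, str], CorrelationEstimate]
    level: float
    seed: int

    def estimate(self, set_name: str, parameter: str) -> CorrelationEstimate:
        key = (set_name, parameter)
        if key not in self.estimates:
            raise KeyError(f"no estimate for set {set_name!r}, parameter {parameter!r}")
        return self.estimates[key]

    def difference(self, set_a: str, set_b: str, parameter: str) -> DifferenceEstimate:
        """Zou interval for rho(set_a) - rho(set_b) on one parameter."""
        return correlation_difference_ci(
            self.estimate(set_a, parameter), self.estimate(set_b, parameter),
            level=self.level,
        )

    def summary(self) -> str:
        lines = [
            "Spearman correlation of translational parameters within pairs",
            f"confidence level: {self.level:.0%}   orientation seed: {self.seed}",
            "",
        ]
        show = self.frame.copy()
        for col in ("rho", "ci_low", "ci_high"):
            show[col] = show[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "--")
        lines.append(show[["set", "parameter", "n", "rho", "ci_low", "ci_high"]]
                     .to_string(index=False))
        return "\n".join(lines)


@dataclass
class FoldChangeResults:
    """Fold-change tightness summaries per interaction set."""

    model: CoregulationModel
    parameter: str
    frame: pd.DataFrame
    samples: dict[str, tuple[np.ndarray, np.ndarray]]  # set -> (fc, log fc)
    reps: int
    method: str
    level: float
    seed: int

    def difference(self, set_a: str, set_b: str,
                   statistic: str = "median") -> BootstrapInterval:
        """Bootstrap CI for statistic(set_a) - statistic(set_b).

        ``statistic="median"`` compares fold-change medians;
        ``"sd"`` compares log-fold-change standard deviations. Both
        argument orders are meaningful (the interval mirrors).
        """
        for name in (set_a, set_b):
            if name not in self.samples:
                raise KeyError(f"no fold-change sample for set {name!r}")
        ia = 0 if statistic == "median" else 1
        return bootstrap_difference_ci(
            self.samples[set_a][ia], self.samples[set_b][ia],
            statistic=statistic, reps=self.reps, method=self.method,
            level=self.level,
            seed=_spawn_seed(self.seed, "diff", set_a, set_b, statistic),
        )

    def all_differences(self, statistic: str = "median") -> pd.DataFrame:
        """All ordered set pairs (both orderings, as controls are compared twice)."""
        names = [n for n in self.samples]
        rows = []
        for a in names:
            for b in names:
                if a == b:
                    continue
                d = self.difference(a, b, statistic=statistic)
                rows.append({"set_a": a, "set_b": b, "statistic": statistic,
                             "delta": d.estimate, "ci_low": d.ci_low,
                             "ci_high": d.ci_high})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Within-pair fold change of {self.parameter} (larger/smaller, >= 1)",
            f"bootstrap: {self.reps} resamples, {self.method} CIs, "
            f"level {self.level:.0%}, natural-log sd",
            "",
        ]
        show = self.frame.copy()
        for col in show.columns:
            if show[col].dtype.kind == "f":
                show[col] = show[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "--")
        lines.append(show.to_string(index=False))
        return "\n".join(lines)


@dataclass
class HubResults:
    """Hub-class correlation survey and party-minus-date differences."""

    model: CoregulationModel
    correlations: pd.DataFrame
    difference_frame: pd.DataFrame
    estimates: dict[tuple[str, str, str], CorrelationEstimate]
    differences: dict[tuple[str, str], DifferenceEstimate]
    level: float

    def estimate(self, hub_class: str, network: str, parameter: str) -> CorrelationEstimate:
        key = (hub_class, network, parameter)
        if key not in self.estimates:
            raise KeyError(f"no estimate for {key}")
        return self.estimates[key]

    def difference(self, network: str, parameter: str) -> DifferenceEstimate:
        key = (network, parameter)
        if key not in self.differences:
            raise KeyError(f"no party-date difference for {key}")
        return self.differences[key]

    def summary(self) -> str:
        lines = [
            "Hub-partner correlation by hub class",
            f"confidence level: {self.level:.0%}",
            "",
            self.correlations.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "party minus date (Zou interval):",
            self.difference_frame.to_string(index=False, float_format=lambda v: f"{v:.3f}")
            if len(self.difference_frame) else "  (none)",
        ]
        return "\n".join(lines)
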