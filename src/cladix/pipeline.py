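"""End-to-end analysis driver.

Chains the full workflow: heuristic search → collapse → consensus trees
→ supports → time calibration and ghost lineages → stratigraphic
congruence → the three ancestral-area passes (PB: parsimony; LEB:
likelihood, equal branch lengths; LFR: likelihood, ghost-lineage branch
lengths).  Every stage is a pure function of the inputs and the seed, so
re-running a manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from cladix.biogeography import (assign_branch_lengths, marginal_areas,
                                 parsimony_areas)
from cladix.matrix import (AgeTable, AreaTable, CharacterMatrix,
                           write_matrix)
from cladix.parsimony import changes_table, fitch_length, unambiguous_changes
from cladix.search import (SearchConfig, SearchResult, bootstrap_supports,
                           bremer_supports, heuristic_search)
from cladix.stratigraphy import calibrate, metrics_under_uncertainty
from cladix.tree import Tree, majority_rule_consensus, write_newick

__all__ = ["RunManifest", "run_full_analysis"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str]
    stage_timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def as_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed,
             "input_digests": self.input_digests,
             "stage_timings": self.stage_timings,
             "outputs": self.outputs, "summary": self.summary},
            indent=1, sort_keys=True)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_full_analysis(matrix: CharacterMatrix, ages: AgeTable,
                      areas: AreaTable,
                      config: SearchConfig | None = None,
                      out_dir: str | Path | None = None,
                      n_bootstrap: int = 0,
                      with_bremer: bool = False) -> RunManifest:
    """Run the complete workflow; returns a manifest of what was done.

    Bootstrap and Bremer passes are opt-in (they multiply search cost).
    When ``out_dir`` is given, consensus trees, the calibrated tree, the
    change list, the stratigraphic metrics and the three area
    reconstruction tables are written there.
    """
    config = config or SearchConfig()
    ages.validate_against(matrix.taxon_names)
    manifest = RunManifest(
        config=asdict(config) | {"constraints": [
            {"mode": c.mode, "taxa": sorted(c.clade)}
            for c in config.constraints]},
        seed=config.seed,
        input_digests={
            "matrix": _digest(write_matrix(matrix)),
            "ages": _digest(json.dumps(sorted(ages.ages.items()))),
            "areas": _digest(json.dumps(sorted(areas.areas.items()))),
        })

    def stage(name: str):
        t0 = time.perf_counter()

        def done() -> None:
            manifest.stage_timings[name] = round(time.perf_counter() - t0, 3)
        return done

    artifacts: dict[str, str] = {}

    end = stage("search")
    result: SearchResult = heuristic_search(matrix, config)
    end()
    score = fitch_length(result.mpts[0], matrix)
    manifest.summary["best_length"] = result.best_length
    manifest.summary["n_mpts"] = len(result.mpts)
    manifest.summary["ci"] = round(score.ci, 4)
    manifest.summary["ri"] = round(score.ri, 4)
    manifest.summary["rci"] = round(score.rci, 4)

    end = stage("consensus")
    strict = result.consensus()
    majority = majority_rule_consensus(result.mpts)
    end()
    artifacts["strict_consensus.nwk"] = write_newick(strict)
    artifacts["majority_consensus.nwk"] = write_newick(
        majority, include_support=True)

    if n_bootstrap > 0:
        end = stage("bootstrap")
        boot = bootstrap_supports(matrix, config,
                                  n_pseudoreplicates=n_bootstrap)
        end()
        artifacts["bootstrap.json"] = json.dumps(
            {"|".join(sorted(c)): v for c, v in sorted(
                boot.items(), key=lambda kv: sorted(kv[0]))}, indent=1)
    if with_bremer:
        end = stage("bremer")
        brem = bremer_supports(matrix, result, config)
        end()
        artifacts["bremer.json"] = json.dumps(
            {"|".join(sorted(c)): v for c, v in sorted(
                brem.items(), key=lambda kv: sorted(kv[0]))}, indent=1)

    end = stage("synapomorphies")
    changes = unambiguous_changes(result.mpts, matrix)
    consensus_clades = strict.clades(include_trivial=True)
    changes = [c for c in changes if c.clade in consensus_clades]
    end()
    artifacts["unambiguous_changes.tsv"] = changes_table(changes)
    manifest.summary["n_unambiguous_changes"] = len(changes)

    end = stage("calibration")
    ct = calibrate(strict, ages, "oldest")
    end()
    artifacts["calibrated_tree.nwk"] = write_newick(_with_ghost_lengths(ct))
    manifest.summary["mig_consensus"] = round(ct.mig(), 1)

    end = stage("stratigraphy")
    metrics = metrics_under_uncertainty(strict, ages, seed=config.seed)
    end()
    artifacts["strat_metrics.json"] = json.dumps(metrics.as_dict(), indent=1)
    manifest.summary["ger_range"] = list(metrics.ger)

    end = stage("biogeography")
    pb = parsimony_areas(strict, areas)
    unit_tree = assign_branch_lengths(strict, "unit")
    leb = marginal_areas(unit_tree, areas)
    ghost_tree = assign_branch_lengths(strict, "ghost", ages)
    lfr = marginal_areas(ghost_tree, areas)
    end()
    artifacts["areas_pb.tsv"] = pb.table()
    artifacts["areas_leb.tsv"] = leb.table()
    artifacts["areas_lfr.tsv"] = lfr.table()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, text in artifacts.items():
            (out / name).write_text(text)
            manifest.outputs[name] = str(out / name)
        (out / "manifest.json").write_text(manifest.as_json())
    else:
        manifest.outputs = {name: _digest(text)
                            for name, text in artifacts.items()}
    return manifest


def _with_ghost_lengths(ct) -> Tree:
    out = ct.tree.copy()
    src = list(ct.tree.postorder())
    dst = list(out.postorder())
    for a, b in zip(src, dst):
        if a.parent is not None:
            b.length = ct.ghost[id(a)]
    return out
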