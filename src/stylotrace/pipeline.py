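"""End-to-end orchestration: QC -> concordance -> locus selection -> trait
recoding -> Mk ladder + ASR + transition tally -> BiSSE ladder over a tree
sample -> report bundle.

The pipeline is a pure function of its configuration and inputs: given the
same seeds it emits byte-identical JSON.  When file inputs are not supplied
it runs on the synthetic study fixture, so the full analysis is exercisable
without downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import bisse as bisse_mod
from . import concordance as conc
from . import mk as mk_mod
from . import simulate as sim
from . import traits as traits_mod
from . import trees as trees_mod
from .characters import FIVE_STATES, CharacterMatrix

log = logging.getLogger(__name__)

ALL_STAGES = ("qc", "concordance", "geneshop", "traits", "mk", "bisse")


@dataclass
class RunConfig:
    """Configuration for a full analysis run (study defaults pre-filled)."""

    seed: int = 1
    out_dir: str = "stylotrace_run"
    stages: tuple[str, ...] = ALL_STAGES
    # input paths (None -> synthetic fixture)
    species_tree: Optional[str] = None
    tree_sample: Optional[str] = None
    gene_tree_dir: Optional[str] = None
    alignment_dir: Optional[str] = None
    traits_csv: Optional[str] = None
    qc_tsv: Optional[str] = None
    # thresholds
    het_cutoff: float = 3.0
    min_loci_per_sample: int = 50
    min_fraction_samples_per_locus: float = 1.0 / 3.0
    rf_cutoff: float = 0.15
    k_loci: int = 12
    n_species_assumed: int = 200
    # models
    mk_schemes: tuple[str, ...] = ("ER", "SYM", "ARD")
    mk_root_modes: tuple[str, ...] = ("weighted", "fixed:tristyly")
    bisse_root_mode: str = "weighted"
    n_posterior: int = 100
    bisse_posterior_subsample: int = 25
    n_starts_mk: int = 3
    n_starts_bisse: int = 2
    # synthetic-concordance scale
    n_synth_loci: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("het_cutoff", "min_loci_per_sample", "rf_cutoff", "k_loci",
                     "n_species_assumed"):
            if getattr(cfg, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return cfg


def _synthetic_concordance_inputs(tree: dendropy.Tree, cfg: RunConfig):
    """Gene trees, alignments and a QC table emulating a target-capture set."""
    rng = np.random.default_rng(cfg.seed + 7)
    taxa = trees_mod.tip_labels(tree)
    gene_trees: dict[str, dendropy.Tree] = {}
    occupancy: dict[str, set] = {}
    alignments: dict[str, dict[str, str]] = {}
    rows = []
    for i in range(cfg.n_synth_loci):
        locus = f"g{4000 + i}"
        n_moves = int(rng.integers(0, 4))
        gt = sim.perturb_topology(tree, n_moves, seed=int(rng.integers(2**31 - 1)))
        # random occupancy dropout on a few loci
        drop = []
        if rng.random() < 0.3:
            drop = list(rng.choice(taxa, size=int(rng.integers(1, 4)), replace=False))
            gt = trees_mod.prune_taxa(gt, drop)
        gene_trees[locus] = gt
        present = [t for t in taxa if t not in drop]
        occupancy[locus] = set(present)
        length = int(rng.integers(200, 800))
        alignments[locus] = {
            t: "".join(rng.choice(list("ACGT"), size=length)) for t in present
        }
        for t in taxa:
            het = float(rng.uniform(0, 2.0)) if i >= 2 else float(rng.uniform(3.5, 6.0))
            rows.append({"locus": locus, "sample": t, "het_pct": het,
                         "recovered": t in present})
    qc = conc.QCTable(pd.DataFrame(rows))
    return gene_trees, occupancy, alignments, qc


@dataclass
class RunBundle:
    config: RunConfig
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.outputs, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_full_analysis(config: RunConfig) -> RunBundle:
    """Run the configured stages and write the report bundle.

    Partial outputs are retained if a later stage fails; the failing stage's
    name is attached to the raised error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = RunBundle(config)
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        if config.species_tree:
            tree = trees_mod.read_trees(config.species_tree)[0]
            sample = (
                trees_mod.read_trees(config.tree_sample)
                if config.tree_sample
                else sim.jitter_tree_sample(tree, config.n_posterior, 0.1, config.seed)
            )
            if config.traits_csv:
                chars5 = CharacterMatrix.from_csv(config.traits_csv, FIVE_STATES,
                                                  column="state_5")
            else:
                chars5, _ = traits_mod.load_fixture()
            chars_binary, pruned = traits_mod.to_binary(chars5)
            binary_tree = trees_mod.prune_taxa(tree, [t for t in pruned
                                                      if t in trees_mod.tip_labels(tree)])
        else:
            fx = sim.make_study_fixture(config.seed, n_posterior=config.n_posterior)
            tree, sample = fx.tree, fx.sample
            chars5, chars_binary = fx.chars5, fx.chars_binary
            pruned, binary_tree = fx.binary_pruned, fx.binary_tree
        mcc = trees_mod.summarize_mcc(sample)
        bundle.outputs["inputs"] = {
            "n_tips": len(trees_mod.tip_labels(tree)),
            "n_posterior_trees": len(sample),
            "synthetic": config.species_tree is None,
        }

        # ---- QC ---------------------------------------------------------
        gene_trees = occupancy = alignments = qc = None
        need_conc = any(s in config.stages for s in ("qc", "concordance", "geneshop"))
        if need_conc:
            if config.gene_tree_dir:
                paths = sorted(Path(config.gene_tree_dir).glob("*.nwk")) + sorted(
                    Path(config.gene_tree_dir).glob("*.tre"))
                gene_trees = {p.stem: trees_mod.read_trees(p)[0] for p in paths}
                occupancy = {k: set(trees_mod.tip_labels(t)) for k, t in gene_trees.items()}
                alignments = (
                    conc.read_alignments(sorted(Path(config.alignment_dir).glob("*.fasta")))
                    if config.alignment_dir else {}
                )
                qc = conc.QCTable.from_tsv(config.qc_tsv) if config.qc_tsv else None
            else:
                gene_trees, occupancy, alignments, qc = _synthetic_concordance_inputs(
                    tree, config)

        if "qc" in config.stages and qc is not None:
            stage = "qc"
            res = conc.qc_filter(
                qc,
                het_cutoff=config.het_cutoff,
                min_loci_per_sample=config.min_loci_per_sample,
                min_fraction_samples_per_locus=config.min_fraction_samples_per_locus,
            )
            log.info("qc: kept %d loci, %d samples; %d exclusions",
                     len(res.kept_loci), len(res.kept_samples), len(res.exclusions))
            bundle.outputs["qc"] = {
                "kept_loci": res.kept_loci,
                "kept_samples": res.kept_samples,
                "exclusions": res.exclusions,
                "thresholds": {
                    "het_cutoff": config.het_cutoff,
                    "min_loci_per_sample": config.min_loci_per_sample,
                    "min_fraction_samples_per_locus": config.min_fraction_samples_per_locus,
                },
            }
            gene_trees = {k: v for k, v in gene_trees.items() if k in res.kept_loci}

        if "concordance" in config.stages and gene_trees:
            stage = "concordance"
            qs = conc.quartet_score(tree, list(gene_trees.values()))
            occ = conc.occupancy_stats(alignments, trees_mod.tip_labels(tree))
            taxa = set(trees_mod.tip_labels(tree))
            # per-clade gts on the species-tree clades
            gts = {}
            for node in tree.preorder_internal_node_iter():
                clade = frozenset(l.taxon.label for l in node.leaf_iter())
                if 2 <= len(clade) <= len(taxa) - 2:
                    gts["|".join(sorted(clade)[:3]) + f"(+{len(clade)})"] = conc.clade_support(
                        list(gene_trees.values()), clade, taxa)
            bundle.outputs["concordance"] = {
                "normalized_quartet_score": qs,
                "occupancy": occ.occupancy,
                "sequence_count": occ.sequence_count,
                "median_bases_per_taxon": occ.median_bases,
                "gts_percent": gts,
            }

        if "geneshop" in config.stages and gene_trees:
            stage = "geneshop"
            shop = conc.gene_shop(gene_trees, tree, occupancy,
                                  k=config.k_loci, rf_cutoff=config.rf_cutoff)
            bundle.outputs["geneshop"] = {
                "selected": shop.selected,
                "warning_fewer_than_k": shop.warning,
                "rf_by_locus": shop.rf_by_locus,
            }

        if "traits" in config.stages:
            stage = "traits"
            bundle.outputs["traits"] = {
                "five_state_counts": dict(chars5.state_counts()),
                "binary_counts": dict(chars_binary.state_counts()),
                "binary_pruned_taxa": pruned,
                "n_five_state_scored": chars5.non_missing(),
                "n_binary_scored": chars_binary.non_missing(),
            }

        if "mk" in config.stages:
            stage = "mk"
            fits = [
                mk_mod.fit_mk(mcc, chars5, mk_mod.MkModelSpec(5, scheme),
                              root_mode="weighted", n_starts=config.n_starts_mk,
                              seed=config.seed + i)
                for i, scheme in enumerate(config.mk_schemes)
            ]
            table = mk_mod.compare_models(fits)
            best = fits[int(np.argmin([f.aicc for f in fits]))]
            best_model = mk_mod.MkModelSpec(5, best.model_id.split("-")[1])
            asr_out = {}
            tally_out = {}
            for root_mode in config.mk_root_modes:
                asr = mk_mod.asr_marginal(mcc, chars5, best_model, best.theta, root_mode)
                total, per_pair = mk_mod.tally_transitions(mcc, chars5, asr)
                root_clade = frozenset(trees_mod.tip_labels(mcc))
                asr_out[root_mode] = {
                    "root_probs": dict(zip(FIVE_STATES,
                                           map(float, asr.probs[root_clade]))),
                    "n_nodes": len(asr.probs),
                }
                tally_out[root_mode] = {
                    "total": total,
                    "per_pair": {f"{a}->{b}": c for (a, b), c in per_pair.items()},
                }
            bundle.outputs["mk"] = {
                "comparison": table,
                "best_model": best.model_id,
                "asr": asr_out,
                "transitions": tally_out,
            }

        if "bisse" in config.stages:
            stage = "bisse"
            rho = chars_binary.non_missing() / config.n_species_assumed
            sub = list(sample)[: config.bisse_posterior_subsample]
            pruned_sample = [
                trees_mod.prune_taxa(t, [x for x in pruned
                                         if x in trees_mod.tip_labels(t)])
                for t in sub
            ]
            summary = bisse_mod.fit_over_posterior(
                pruned_sample, chars_binary, rho=rho,
                root_mode=config.bisse_root_mode,
                n_starts=config.n_starts_bisse, seed=config.seed,
            )
            bundle.outputs["bisse"] = {
                "rho": rho,
                "n_trees": summary.n_trees,
                "n_failed": summary.n_failed,
                "table": summary.to_dataframe(),
                "best_model": summary.best.name,
            }

        stage = "write"
        (out_dir / "bundle.json").write_text(bundle.to_json())
        for name, obj in bundle.outputs.items():
            if isinstance(obj, dict) and isinstance(obj.get("table"), pd.DataFrame):
                obj["table"].to_csv(out_dir / f"{name}_table.tsv", sep="\t", index=False)
        if "mk" in bundle.outputs:
            bundle.outputs["mk"]["comparison"].to_csv(
                out_dir / "mk_comparison.tsv", sep="\t", index=False)
        (out_dir / "report.txt").write_text(render_report(bundle))
        return bundle
    except Exception as err:
        # retain partial outputs for debugging before re-raising
        try:
            (out_dir / "bundle.partial.json").write_text(bundle.to_json())
        except Exception:
            pass
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def render_report(bundle: RunBundle) -> str:
    """Human-readable summary of a run bundle (idempotent)."""
    lines: list[str] = ["stylotrace analysis report", "=" * 26, ""]
    out = bundle.outputs
    if "qc" in out:
        lines += [
            f"QC: kept {len(out['qc']['kept_loci'])} loci, "
            f"{len(out['qc']['kept_samples'])} samples; "
            f"{len(out['qc']['exclusions'])} exclusions",
        ]
    if "concordance" in out:
        c = out["concordance"]
        lines += [
            f"Concordance: normalized quartet score {c['normalized_quartet_score']:.3f}; "
            f"occupancy {100 * c['occupancy']:.1f}% "
            f"({c['sequence_count']} sequences)",
        ]
    if "geneshop" in out:
        lines += [f"Gene shopping: selected {len(out['geneshop']['selected'])} loci: "
                  + ", ".join(out['geneshop']['selected'])]
    if "mk" in out:
        lines += ["", "Mk-n model comparison:",
                  out["mk"]["comparison"].to_string(index=False)]
        for mode, t in out["mk"]["transitions"].items():
            lines.append(f"  transitions ({mode} root): {t['total']}")
        for mode, a in out["mk"]["asr"].items():
            probs = ", ".join(f"{k}={v:.2f}" for k, v in a["root_probs"].items())
            lines.append(f"  root marginals ({mode}): {probs}")
    if "bisse" in out:
        b = out["bisse"]
        lines += ["", f"BiSSE ladder over {b['n_trees']} trees (rho={b['rho']:.3f}); "
                  f"best model (*): {b['best_model']}",
                  b["table"].to_string(index=False)]
    lines.append("")
    return "\n".join(lines)
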