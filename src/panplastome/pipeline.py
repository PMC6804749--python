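"""End-to-end orchestration: structure -> gap filter -> haplotypes -> pans ->
diversity -> per-locus variation -> delimitation -> network -> markers.

Every run writes a reproducibility manifest (the verbatim configuration,
its hash, and the package version) next to its outputs; reruns with the
same configuration and inputs reproduce byte-identical tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import load_alignment, load_groups, load_locus_table, load_tree, write_fasta
from .loci import (GroupHierarchy, locus_lengths, locus_size_deviation,
                   partition_variants_by_locus, reports_to_frame)
from .markers import select_candidates, signal_check
from .matrix import AlignedMatrix, LocusTable
from .pan import build_all_pans, mask_ambiguous_columns
from .phylo import (delimit_species, minimum_spanning_network, nj_tree,
                    pdistance_matrix)
from .popgen import diversity_stats
from .repeats import polymorphic_repeat_loci
from .sites import classify_sites, collapse_haplotypes, detect_indel_events, filter_gap_columns

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment: str
    groups: str | None = None
    loci: str | None = None
    tree: str | None = None
    outgroup: str | None = None
    composites: dict[str, list[str]] = field(default_factory=dict)
    max_gap_fraction: float = 0.996
    gap_mode: str = "gaps_as_state"
    marker_min_groups: int = 4
    marker_min_h: int = 4
    kscore_max: float = 0.01
    msn_epsilon: int = 0
    seed: int = 0
    outdir: str = "panplastome_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; outputs land in ``config.outdir``.

    Stages requiring missing inputs (groups, loci, tree) are skipped with
    a warning; any stage error aborts with the stage name, preserving the
    outputs already written.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": json.loads(config.to_json()),
                "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
                "version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    summary: dict = {}
    stage = "load"
    try:
        m = load_alignment(config.alignment, config.groups)
        stage = "filter"
        m, col_map = filter_gap_columns(m, config.max_gap_fraction)
        np.savetxt(out / "column_map.tsv.gz", col_map, fmt="%d")
        stage = "sites"
        cls = classify_sites(m)
        summary["sites"] = {"n": m.n, "length": m.length, "S": cls.S,
                            "Eta": cls.Eta, "singletons": cls.n_singleton,
                            "parsimony_informative": cls.n_pi}
        logger.info("sites: %s", summary["sites"])
        stage = "indels"
        events = detect_indel_events(m)
        pd.DataFrame([(e.start, e.end, e.length, ";".join(sorted(e.pattern)))
                      for e in events],
                     columns=["start", "end", "length", "gapped_ids"]
                     ).to_csv(out / "indel_events.tsv", sep="\t", index=False)
        summary["indel_events"] = len(events)
        stage = "haplotypes"
        haps = collapse_haplotypes(m, config.gap_mode)
        pd.DataFrame([(h.members[0], h.count, ";".join(h.members)) for h in haps],
                     columns=["representative", "count", "members"]
                     ).to_csv(out / "haplotypes.tsv", sep="\t", index=False)
        summary["haplotypes"] = len(haps)
        stage = "diversity"
        div = diversity_stats(m, config.gap_mode)
        (out / "diversity.json").write_text(json.dumps(dataclasses.asdict(div), indent=1))
        summary["diversity"] = dataclasses.asdict(div)

        if not m.groups:
            logger.warning("no group table: pan, loci, delimitation, network "
                           "and marker stages skipped")
            return summary

        stage = "pan"
        pans = build_all_pans(m)
        write_fasta({p.group: p.sequence for p in pans}, out / "pans.fasta")
        masked, kept = mask_ambiguous_columns(pans)
        write_fasta(masked, out / "pans_masked.fasta")
        summary["pans"] = {"n_groups": len(pans), "masked_columns": int((~kept).sum())}

        hier = None
        if config.outgroup:
            leaves = [g for g in masked.ids if g != config.outgroup]
            hier = GroupHierarchy(
                leaves=leaves,
                composites={k: frozenset(v) for k, v in config.composites.items()},
                reference=config.outgroup)

        loci = None
        if config.loci:
            stage = "loci"
            loci = load_locus_table(config.loci, length=m.length)
            if hier is not None:
                reports = partition_variants_by_locus(masked, loci, hier, pans)
                reports_to_frame(reports).to_csv(out / "locus_variants.tsv",
                                                 sep="\t", index=False)
                summary["loci"] = {"n_loci": len(reports),
                                   "total_snps": sum(r.n_snps for r in reports)}
            stage = "repeats"
            reps = polymorphic_repeat_loci(pans, loci, members=m)
            reps.to_csv(out / "repeats.tsv", sep="\t", index=False)
            summary["repeats"] = {"n": len(reps),
                                  "polymorphic": int(reps["polymorphic"].sum())
                                  if not reps.empty else 0}
            stage = "size_deviation"
            dev = locus_size_deviation(locus_lengths(m, loci),
                                       config.outgroup or m.group_labels()[0])
            dev.to_csv(out / "locus_size_deviation.tsv", sep="\t")

        stage = "tree"
        if config.tree:
            tree = load_tree(config.tree)
        else:
            tree = nj_tree(pdistance_matrix(m))
        tree.write(path=str(out / "accession_tree.nwk"), schema="newick")

        if config.outgroup:
            stage = "delimit"
            rows = delimit_species(tree, m.groups, config.outgroup)
            pd.DataFrame([dataclasses.asdict(r) for r in rows]
                         ).to_csv(out / "delimitation.tsv", sep="\t", index=False)
            summary["delimitation"] = {
                "groups": len(rows),
                "monophyletic": sum(r.monophyletic for r in rows)}

        stage = "network"
        net = minimum_spanning_network(haps, config.msn_epsilon)
        pd.DataFrame([(u, v, d["weight"]) for u, v, d in net.edges(data=True)],
                     columns=["u", "v", "weight"]
                     ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        summary["network"] = {"nodes": net.number_of_nodes(),
                              "edges": net.number_of_edges()}

        if loci is not None and hier is not None:
            stage = "markers"
            reports = partition_variants_by_locus(masked, loci, hier, pans)
            pan_tree = nj_tree(pdistance_matrix(masked))
            selected, unneutral = select_candidates(
                reports, config.marker_min_groups, config.marker_min_h)
            checked = [signal_check(c, masked, loci, pan_tree,
                                    kscore_max=config.kscore_max)
                       for c in selected]
            pd.DataFrame([{
                "loci": "+".join(c.loci), "n_snps": c.n_snps, "h": c.h,
                "variable_in_groups": c.variable_in_groups,
                "rf": c.comparison.rf_distance if c.comparison else None,
                "k_score": c.comparison.k_score if c.comparison else None,
                "signal_retrieved": c.signal_retrieved,
                "discriminated_groups": ";".join(sorted(c.discriminated_groups)),
            } for c in checked]).to_csv(out / "marker_candidates.tsv",
                                        sep="\t", index=False)
            summary["markers"] = {"selected": len(selected),
                                  "unneutral": len(unneutral)}
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, exc) from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
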