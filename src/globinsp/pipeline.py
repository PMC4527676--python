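"""End-to-end workflows wiring the analysis stages together.

Two compositions are provided. The sequence workflow takes a gapped MSA
containing an annotated reference row and produces a fold-check report,
tandem-domain calls with split domains, a redundancy-reduced id list and a
bootstrap-supported NJ tree. The structure workflow takes two or more
C-alpha traces plus an alignment (or builds a structure-guided fallback)
and produces per-pair dRMSD profiles, their column-wise average, a summary
table and least-squares superposition transforms.

Every run writes a manifest recording input digests, parameters, the seed
and the package version; all randomness flows from that single seed, so
deterministic outputs are byte-identical on rerun.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .domain_scan import scan_domains, split_domains
from .globin_fold import check_mb_fold, default_reference, MbFoldTemplate
from .io_formats import (
    SequenceRecord,
    StructAlignment,
    attach_confidence,
    read_confidence,
    read_msa,
    read_structure,
    write_fasta,
    write_matrix_tsv,
    write_newick,
)
from .phylo_nj import bootstrap_support
from .redundancy import build_matrix, reduce_redundancy
from .struct_compare import (
    average_profiles,
    intra_distances,
    per_site_drmsd,
    profile_table,
    structure_guided_alignment,
    superpose,
)

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, inputs: dict[str, str], parameters: dict,
                    seed: int) -> None:
    manifest = {
        "tool": "globinsp",
        "version": __version__,
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


class StageError(RuntimeError):
    """An error in a named workflow stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class SequenceWorkflowConfig:
    msa_path: str
    out_dir: str
    reference_id: str | None = None  # default: the shipped reference id
    template_variant: str = "methods"
    redundancy_threshold: float = 90.0
    min_domain_score: float = 60.0
    bootstrap_replicates: int = 100
    seed: int = 1234
    fugue_z: dict[str, float] = field(default_factory=dict)


def run_sequence_workflow(config: SequenceWorkflowConfig) -> Path:
    """Fold check → domain scan → redundancy reduction → NJ tree."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    msa_path = Path(config.msa_path)

    reference, annotation = default_reference()
    ref_id = config.reference_id or reference.id
    template = MbFoldTemplate.default(config.template_variant)

    try:
        msa = read_msa(msa_path.read_text())
    except ValueError as exc:
        raise StageError("read_msa", str(exc)) from exc
    ids = [r.id for r in msa]
    if ref_id not in ids:
        raise StageError("fold_check", f"reference {ref_id!r} not in the MSA")
    ref_row = next(r for r in msa if r.id == ref_id)

    # --- fold check, one candidate row at a time against the reference
    fold_rows = []
    for rec in msa:
        if rec.id == ref_id:
            continue
        pair = StructAlignment.from_gapped([ref_row, rec])
        try:
            result = check_mb_fold(
                pair, template, annotation,
                fugue_z=config.fugue_z.get(rec.id),
            )
        except (ValueError, KeyError) as exc:
            raise StageError("fold_check", f"{rec.id}: {exc}") from exc
        fold_rows.append({
            "id": rec.id,
            "f8_his": result.f8_his,
            "helices_present": "".join(sorted(result.helices_present)),
            "hydrophobic_fraction": round(result.hydrophobic_fraction, 4),
            "fugue_z": result.fugue_z,
            "verdict": "pass" if result.verdict else "fail",
        })
    pd.DataFrame(fold_rows).to_csv(out_dir / "fold_check.tsv", sep="\t",
                                   index=False)

    # --- tandem-domain scan of every candidate, probe = reference
    f8_ordinal = annotation.ordinal_of("F8")
    domain_rows = []
    all_domains: list[SequenceRecord] = []
    for rec in msa:
        if rec.id == ref_id:
            continue
        query = SequenceRecord(rec.id, rec.ungapped)
        if len(query.ungapped) < len(reference.sequence):
            continue
        calls = scan_domains(query, reference, config.min_domain_score,
                             f8_ordinal=f8_ordinal)
        for call in calls:
            domain_rows.append({
                "id": rec.id, "start": call.start, "end": call.end,
                "score": round(call.score, 1), "f8_his": call.f8_his,
            })
        all_domains.extend(split_domains(query, calls))
    pd.DataFrame(domain_rows).to_csv(out_dir / "domains.tsv", sep="\t",
                                     index=False)
    if all_domains:
        (out_dir / "domains.fasta").write_text(write_fasta(all_domains))

    # --- redundancy reduction over the candidate rows
    candidates = [r for r in msa if r.id != ref_id]
    matrix = build_matrix(candidates)
    kept = reduce_redundancy(matrix, config.redundancy_threshold)
    (out_dir / "similarity.tsv").write_text(
        write_matrix_tsv(matrix.ids, matrix.values)
    )
    (out_dir / "kept_ids.txt").write_text("\n".join(kept) + "\n")

    # --- NJ tree with bootstrap supports over the kept rows
    kept_msa = [r for r in candidates if r.id in set(kept)]
    if len(kept_msa) >= 4:
        try:
            tree = bootstrap_support(kept_msa, config.bootstrap_replicates,
                                     seed=config.seed)
        except ValueError as exc:
            raise StageError("nj_tree", str(exc)) from exc
        (out_dir / "tree.nwk").write_text(write_newick(tree))
    else:
        logger.warning("fewer than 4 non-redundant sequences; no tree built")

    _write_manifest(
        out_dir,
        inputs={msa_path.name: _digest(msa_path)},
        parameters={
            "reference_id": ref_id,
            "template_variant": config.template_variant,
            "redundancy_threshold": config.redundancy_threshold,
            "min_domain_score": config.min_domain_score,
            "bootstrap_replicates": config.bootstrap_replicates,
        },
        seed=config.seed,
    )
    return out_dir


@dataclass
class StructureWorkflowConfig:
    structure_paths: list[str]
    out_dir: str
    alignment_path: str | None = None  # None: structure-guided fallback
    confidence_path: str | None = None
    target_id: str | None = None  # default: first structure
    chains: dict[str, str] = field(default_factory=dict)
    seed: int = 1234


def run_structure_workflow(config: StructureWorkflowConfig) -> Path:
    """Distance matrices → per-pair dRMSD profiles → average → superposition."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in config.structure_paths]
    if len(paths) < 2:
        raise StageError("read_structures", "need at least 2 structures")

    traces = []
    for path in paths:
        sid = path.stem
        try:
            traces.append(read_structure(path.read_text(),
                                         chain=config.chains.get(sid),
                                         structure_id=sid))
        except ValueError as exc:
            raise StageError("read_structures", f"{sid}: {exc}") from exc
    by_id = {t.structure_id: t for t in traces}

    if config.alignment_path is not None:
        from .io_formats import read_gapped_alignment

        aln = read_gapped_alignment(Path(config.alignment_path).read_text())
        alignment_source = "external"
    else:
        aln = structure_guided_alignment(traces)
        alignment_source = "structure-guided fallback"
    if config.confidence_path is not None:
        conf = read_confidence(Path(config.confidence_path).read_text())
        aln = attach_confidence(aln, conf)

    target = config.target_id or traces[0].structure_id
    if target not in by_id:
        raise StageError("profiles", f"unknown target structure {target!r}")
    dmats = {t.structure_id: intra_distances(t) for t in traces}

    profiles = []
    summary_rows = []
    transforms = {}
    for trace in traces:
        sid = trace.structure_id
        if sid == target:
            continue
        profile = per_site_drmsd(dmats[sid], dmats[target], aln)
        profiles.append(profile)
        profile_table(profile).to_csv(
            out_dir / f"profile_{sid}_vs_{target}.tsv", sep="\t", index=False,
            float_format="%.4f",
        )
        summary_rows.append({
            "pair": f"{sid}|{target}",
            "n_aligned": profile.n_aligned,
            "overall_rmsd": round(profile.overall_rmsd, 4),
        })
        sup = superpose(by_id[target], trace, aln)
        transforms[sid] = {
            "rotation": np.round(sup.rotation, 6).tolist(),
            "translation": np.round(sup.translation, 6).tolist(),
            "coordinate_rmsd": round(sup.coordinate_rmsd, 4),
        }

    if len(profiles) == 2:
        mean_profile = average_profiles(profiles[0], profiles[1])
        profile_table(mean_profile).to_csv(
            out_dir / f"profile_mean_vs_{target}.tsv", sep="\t", index=False,
            float_format="%.4f",
        )
        summary_rows.append({
            "pair": f"mean|{target}",
            "n_aligned": mean_profile.n_aligned,
            "overall_rmsd": round(mean_profile.overall_rmsd, 4),
        })
    pd.DataFrame(summary_rows).to_csv(out_dir / "summary.tsv", sep="\t",
                                      index=False)
    (out_dir / "superpositions.json").write_text(
        json.dumps(transforms, indent=2) + "\n"
    )

    _write_manifest(
        out_dir,
        inputs={p.name: _digest(p) for p in paths},
        parameters={
            "target": target,
            "alignment": alignment_source,
        },
        seed=config.seed,
    )
    return out_dir
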