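"""One-command orchestration: pair → couple → map → hotspots → profile.

A :class:`RunConfig` (defaults match the published analysis settings:
kernel a = b = 0.001, half-window l = 21; contact rule 5 Å / ≥ 2
heavy-atom pairs lives in :mod:`spdca.dynamics`) drives the full
workflow on files, writing every intermediate, a machine-readable
manifest (parameters, package version, SHA-256 of each output) and a
human-readable summary (complex, cMSA depth, predicted interactions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import (
    concatenate_by_species,
    filter_by_similarity,
    read_alignment,
    select_best_isoform,
    write_paired,
)
from .coevolution import (
    coupling_scores,
    fit_plm,
    inter_protein_block,
    sequence_weights,
    write_scores_tsv,
)
from .core import (
    PriorParams,
    convolve,
    extract_hotspots,
    label_hotspots,
    write_hotspots_tsv,
    write_qmap_csv,
)
from .physchem import contrast_table
from .prior import build_prior_mask, parse_topology

logger = logging.getLogger("spdca")


@dataclass
class RunConfig:
    """All knobs of one SP-DCA run; defaults are the published settings."""

    msa_a: str = ""
    msa_b: str = ""
    ref_a: str = ""                 # optional reference FASTA for filtering
    ref_b: str = ""
    topology_a: str = ""            # optional segment tables
    topology_b: str = ""
    name_a: str = "A"
    name_b: str = "B"
    min_id: float = 0.70
    max_id: float = 0.90
    filter_orthologs: bool = False  # identity-band filter needs a reference
    theta: float = 0.8
    reg_fields: float = 0.01
    reg_couplings: float | None = None   # default 0.01·(L−1) at fit time
    apc: bool = True
    a: float = 0.001
    b: float = 0.001
    l: int = 21
    use_prior_masks: bool = True
    top_fraction: float = 0.01
    min_separation: int = 10
    window: int = 9
    seed: int = 0

    def prior_params(self) -> PriorParams:
        return PriorParams(a=self.a, b=self.b, l=self.l)


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a :class:`RunConfig`."""
    cfg = RunConfig()
    types = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if not sep or not hasattr(cfg, key):
            raise ValueError(f"{path}:{lineno}: unknown config line {line!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, _BOOL[val.lower()])
        elif isinstance(current, int) and not isinstance(current, bool):
            setattr(cfg, key, int(val))
        elif isinstance(current, float):
            setattr(cfg, key, float(val))
        elif current is None:
            setattr(cfg, key, None if val.lower() == "none" else float(val))
        else:
            setattr(cfg, key, val)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """Failure inside one pipeline stage; partial outputs are retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the full workflow; returns the run directory.

    Stages: pair (read/filter/concatenate), couple (reweight + plmDCA +
    scores), map (Eq.-style convolution with prior masks), hotspots
    (extract + label), profile (property contrasts on protein A).  Every
    stage's outputs are flushed before the next starts, so a failure
    leaves all earlier intermediates in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    t0 = time.time()

    def stage(name):
        logger.info("stage %-8s +%6.1fs", name, time.time() - t0)

    try:
        stage("pair")
        aln_a = read_alignment(cfg.msa_a, cfg.name_a)
        aln_b = read_alignment(cfg.msa_b, cfg.name_b)
        if cfg.filter_orthologs:
            ref_a = read_alignment(cfg.ref_a).sequence(0)
            ref_b = read_alignment(cfg.ref_b).sequence(0)
            aln_a = select_best_isoform(
                filter_by_similarity(aln_a, ref_a, cfg.min_id, cfg.max_id), ref_a
            )
            aln_b = select_best_isoform(
                filter_by_similarity(aln_b, ref_b, cfg.min_id, cfg.max_id), ref_b
            )
        pa = concatenate_by_species(aln_a, aln_b)
        pair_path = outdir / "pair.fasta"
        write_paired(pa, pair_path)
        outputs += [pair_path, pair_path.with_suffix(".fasta.meta.tsv")]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("pair", exc) from exc

    try:
        stage("couple")
        w = sequence_weights(pa, cfg.theta)
        model = fit_plm(
            pa, w, reg_fields=cfg.reg_fields, reg_couplings=cfg.reg_couplings
        )
        cm = coupling_scores(model, apply_apc=cfg.apc)
        scores_path = outdir / "scores.tsv"
        write_scores_tsv(cm, pa, scores_path)
        outputs.append(scores_path)
        P = inter_protein_block(cm, pa.len_a, pa.len_b)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("couple", exc) from exc

    try:
        stage("map")
        dm_a = parse_topology(cfg.topology_a, cfg.name_a, length=pa.len_a) if cfg.topology_a else None
        dm_b = parse_topology(cfg.topology_b, cfg.name_b, length=pa.len_b) if cfg.topology_b else None
        mask_a = build_prior_mask(dm_a) if (dm_a and cfg.use_prior_masks) else None
        mask_b = build_prior_mask(dm_b) if (dm_b and cfg.use_prior_masks) else None
        conv = convolve(P, cfg.prior_params(), mask_a, mask_b)
        qmap_path = outdir / "qmap.csv"
        write_qmap_csv(conv, qmap_path)
        outputs.append(qmap_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("map", exc) from exc

    try:
        stage("hotspots")
        rects = extract_hotspots(conv, cfg.top_fraction, cfg.min_separation)
        if dm_a is not None and dm_b is not None:
            rects = label_hotspots(rects, dm_a, dm_b)
        hs_path = outdir / "hotspots.tsv"
        write_hotspots_tsv(rects, hs_path)
        outputs.append(hs_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("hotspots", exc) from exc

    try:
        stage("profile")
        if rects:
            # contrast properties of protein A over a consensus-like first row
            seq_a = "".join(pa.rows[0, : pa.len_a])
            table = contrast_table(
                seq_a, rects, axis="A", window=cfg.window, seed=cfg.seed,
                protein=cfg.name_a,
            )
            prof_path = outdir / "property_contrasts.tsv"
            table.to_csv(prof_path, sep="\t", index=False, float_format="%.6g")
            outputs.append(prof_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("profile", exc) from exc

    stage("report")
    summary_path = outdir / "summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write("complex\tcmsa_depth\tcmsa_length\tpredicted_interactions\n")
        labels = ";".join(r.label or f"{r.start_a}-{r.end_a}/{r.start_b}-{r.end_b}" for r in rects)
        fh.write(f"{cfg.name_a}/{cfg.name_b}\t{pa.n_rows}\t{pa.length}\t{labels}\n")
    outputs.append(summary_path)

    manifest = {
        "spdca_version": __version__,
        "config": dataclasses.asdict(cfg),
        "m_eff": float(w.m_eff),
        "model_meta": {k: v for k, v in model.meta.items()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete in %.1fs", time.time() - t0)
    return outdir
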