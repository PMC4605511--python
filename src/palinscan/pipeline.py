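"""End-to-end survey pipeline: scan chains for palindromes, annotate each hit
with structure-derived properties, classify, and emit the annotated hit table
plus summary tables (length histogram, secondary-structure composition for
hits and matched controls, per-length SASA ranges, hydropathy distribution,
unique-sequence tallies, family distribution, chameleons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import classify, properties, struct_annotate
from .palindrome_scan import (ControlWindow, PalindromeHit, ScanConfig,
                              enumerate_palindromes, filter_hits,
                              sample_control_windows, unique_sequences)
from .structure_io import (ChainSequence, StructureModel, chain_sequence,
                           read_dssp, read_structure)

log = logging.getLogger("palinscan")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "read_catalytic_list", "read_chain_list"]

HIT_COLUMNS = [
    "pdb_id", "chain", "description", "start", "end", "location", "sequence",
    "length", "ss_string", "ss_category", "avg_sasa", "n_contacts",
    "avg_hydropathy", "ligand", "metal", "site_or_catalytic", "disulphide",
    "nested", "overlapping", "consecutive", "repeated",
]


@dataclass
class PipelineConfig:
    pdb_paths: Sequence = ()
    chain_list: Optional[set[tuple[str, str]]] = None   # (pdb_id, chain_id)
    dssp_dir: Optional[Path] = None
    catalytic: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    scan: ScanConfig = field(default_factory=ScanConfig)
    probe_radius: float = 1.4
    n_points: int = 960
    contact_cutoff: float = 3.2
    interaction_cutoff: float = 3.9
    ss_rule: classify.SSCategoryRule = field(default_factory=classify.SSCategoryRule)
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        for name in ("probe_radius", "contact_cutoff", "interaction_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    hits: pd.DataFrame
    controls: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    exclusions: list[tuple[str, str, str, str]]   # pdb, chain, window, reason
    failures: list[tuple[str, str]]               # path, error

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def read_chain_list(path) -> set[tuple[str, str]]:
    """Plain-text chain list: one ``PDBID_CHAIN`` (or ``PDBID:CHAIN`` /
    whitespace-separated) entry per line, # comments allowed."""
    out = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("_", ":", "\t", " "):
            if sep in line:
                pdb_id, chain_id = line.split(sep, 1)
                break
        else:
            pdb_id, chain_id = line[:4], line[4:] or "A"
        out.add((pdb_id.strip().upper(), chain_id.strip()))
    return out


def read_catalytic_list(path) -> dict[str, list[tuple[str, int, str]]]:
    """Catalytic residues as TSV: pdb_id, chain, resnum, icode (icode optional)."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        pdb_id, chain_id, num = parts[0].upper(), parts[1], int(parts[2])
        icode = parts[3] if len(parts) > 3 else ""
        out.setdefault(pdb_id, []).append((chain_id, num, icode))
    return out


def _annotate_chain_hits(model: StructureModel, chain: ChainSequence,
                         hits: list[PalindromeHit], ss_chain: str,
                         sasa, cfg: PipelineConfig, exclusions) -> list[dict]:
    rows = []
    kept_hits = []
    for hit in hits:
        ss = ss_chain[hit.start_index:hit.end_index]
        if "-" in ss:
            exclusions.append((model.pdb_id, chain.chain_id,
                               f"{hit.sequence}@{hit.location}",
                               "missing secondary structure"))
            continue
        kept_hits.append((hit, ss))
    modes = classify.detect_modes([h for h, _ in kept_hits])
    for k, (hit, ss) in enumerate(kept_hits):
        category = classify.ss_category(ss, cfg.ss_rule)
        avg_sasa = struct_annotate.average_sasa(model, hit, sasa)
        contacts = struct_annotate.count_contacts(model, hit,
                                                  cutoff=cfg.contact_cutoff)
        flags = struct_annotate.functional_interactions(
            model, hit, catalytic_list=cfg.catalytic.get(model.pdb_id),
            cutoff=cfg.interaction_cutoff)
        ann = modes[k]
        rows.append({
            "pdb_id": model.pdb_id, "chain": chain.chain_id,
            "description": model.compound or model.title,
            "start": hit.location.split("-")[0],
            "end": hit.location.split("-")[-1],
            "location": hit.location,
            "sequence": hit.sequence, "length": hit.length,
            "ss_string": ss, "ss_category": category,
            "avg_sasa": round(avg_sasa, 2),
            "n_contacts": contacts.n_contact_residues,
            "avg_hydropathy": round(
                properties.average_hydrophobicity(hit.sequence), 2),
            "ligand": flags.ligand, "metal": flags.metal,
            "site_or_catalytic": flags.site_or_catalytic,
            "disulphide": flags.disulphide,
            "nested": ann.is_nested,
            "overlapping": bool(ann.overlaps),
            "consecutive": bool(ann.consecutive_with),
            "repeated": ann.repeat_group is not None,
            "_hit": hit,
        })
    return rows


def _summaries(hit_rows: pd.DataFrame, control_rows: pd.DataFrame,
               hits: list[PalindromeHit],
               classifications: dict[str, str]) -> dict[str, pd.DataFrame]:
    s: dict[str, pd.DataFrame] = {}
    lengths = sorted(set(hit_rows["length"]) | set(
        control_rows["length"] if len(control_rows) else []))
    s["length_histogram"] = pd.DataFrame({
        "length": lengths,
        "n_hits": [int((hit_rows["length"] == L).sum()) for L in lengths],
        "n_controls": [int((control_rows["length"] == L).sum())
                       if len(control_rows) else 0 for L in lengths],
    })
    cats = list(classify.CATEGORIES)
    s["ss_composition"] = pd.DataFrame({
        "category": cats,
        "n_hits": [int((hit_rows["ss_category"] == c).sum()) for c in cats],
        "pct_hits": [round(100 * (hit_rows["ss_category"] == c).mean(), 1)
                     if len(hit_rows) else 0.0 for c in cats],
        "n_controls": [int((control_rows["ss_category"] == c).sum())
                       if len(control_rows) else 0 for c in cats],
    })
    rows = []
    for L in lengths:
        hsel = hit_rows[hit_rows["length"] == L]["avg_sasa"]
        csel = (control_rows[control_rows["length"] == L]["avg_sasa"]
                if len(control_rows) else pd.Series(dtype=float))
        rows.append({
            "length": L,
            "hits_min": hsel.min() if len(hsel) else None,
            "hits_max": hsel.max() if len(hsel) else None,
            "controls_min": csel.min() if len(csel) else None,
            "controls_max": csel.max() if len(csel) else None,
        })
    s["sasa_range"] = pd.DataFrame(rows)
    hyd = hit_rows["avg_hydropathy"]
    s["hydropathy"] = pd.DataFrame([{
        "n": len(hyd),
        "min": hyd.min() if len(hyd) else None,
        "max": hyd.max() if len(hyd) else None,
        "n_negative": int((hyd < 0).sum()),
        "n_zero": int((hyd == 0).sum()),
        "n_positive": int((hyd > 0).sum()),
    }])
    uniq = unique_sequences(hits)
    s["unique_sequences"] = pd.DataFrame(
        [{"length": L, "n_unique": len(counter),
          "n_hits": sum(counter.values())}
         for L, counter in sorted(uniq.items())])
    fam = classify.family_distribution(hits, classifications)
    s["family_distribution"] = pd.DataFrame(
        [{"classification": k, "n_hits": v}
         for k, v in sorted(fam.items(), key=lambda kv: (-kv[1], kv[0]))])
    return s


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full survey over the configured structures.

    Per-entry failures are logged and skipped; the result carries a failure
    manifest.  Outputs are deterministic for a fixed config and seed.
    """
    exclusions: list[tuple[str, str, str, str]] = []
    failures: list[tuple[str, str]] = []
    all_rows: list[dict] = []
    chain_seqs: list[ChainSequence] = []
    models: dict[str, StructureModel] = {}
    ss_by_chain: dict[tuple[str, str], str] = {}
    sasa_by_pdb: dict[str, struct_annotate.SasaProfile] = {}

    scan_cfg = replace(cfg.scan, seed=cfg.seed)
    for path in cfg.pdb_paths:
        path = Path(path)
        try:
            model = read_structure(path)
            models[model.pdb_id] = model
            dssp_map = None
            if cfg.dssp_dir is not None:
                for candidate in (Path(cfg.dssp_dir) / f"{model.pdb_id.lower()}.dssp",
                                  Path(cfg.dssp_dir) / f"{model.pdb_id}.dssp"):
                    if candidate.exists():
                        dssp_map = read_dssp(candidate)
                        break
            sasa = struct_annotate.shrake_rupley_sasa(
                model, probe=cfg.probe_radius, n_points=cfg.n_points)
            sasa_by_pdb[model.pdb_id] = sasa
            for chain_id in model.chains:
                if cfg.chain_list is not None and \
                        (model.pdb_id, chain_id) not in cfg.chain_list:
                    continue
                chain = chain_sequence(model, chain_id)
                chain_seqs.append(chain)
                ss_chain = struct_annotate.assign_secondary_structure(
                    model, chain_id, dssp_map=dssp_map)
                ss_by_chain[(model.pdb_id, chain_id)] = ss_chain
                raw_log: list = []
                hits = filter_hits(enumerate_palindromes(chain, scan_cfg),
                                   chain, scan_cfg, exclusion_log=raw_log)
                for h, reason in raw_log:
                    exclusions.append((model.pdb_id, chain_id,
                                       f"{h.sequence}@{h.location}", reason))
                all_rows.extend(_annotate_chain_hits(
                    model, chain, hits, ss_chain, sasa, cfg, exclusions))
        except Exception as exc:
            log.error("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))

    for pdb, ch, window, reason in exclusions:
        log.info("excluded %s:%s %s (%s)", pdb, ch, window, reason)

    hit_df = pd.DataFrame(all_rows, columns=HIT_COLUMNS + ["_hit"])
    hit_df = hit_df.sort_values(
        ["pdb_id", "chain", "length", "sequence", "location"],
        kind="stable").reset_index(drop=True)
    hits = list(hit_df["_hit"]) if len(hit_df) else []

    control_rows: list[dict] = []
    if hits and chain_seqs:
        controls = sample_control_windows(chain_seqs, hits, scan_cfg)
        for ctl in controls:
            ss_chain = ss_by_chain.get((ctl.pdb_id, ctl.chain_id), "")
            ss = ss_chain[ctl.start_index:ctl.end_index]
            model = models.get(ctl.pdb_id)
            avg = None
            cat = None
            if model is not None and ss and "-" not in ss:
                cat = classify.ss_category(ss, cfg.ss_rule)
                pseudo = PalindromeHit(pdb_id=ctl.pdb_id, chain_id=ctl.chain_id,
                                       start_index=ctl.start_index,
                                       sequence=ctl.sequence,
                                       start_pos=ctl.start_pos,
                                       end_pos=ctl.end_pos)
                avg = round(struct_annotate.average_sasa(
                    model, pseudo, sasa_by_pdb[ctl.pdb_id]), 2)
            control_rows.append({
                "pdb_id": ctl.pdb_id, "chain": ctl.chain_id,
                "sequence": ctl.sequence, "length": ctl.length,
                "ss_string": ss, "ss_category": cat, "avg_sasa": avg,
                "avg_hydropathy": round(
                    properties.average_hydrophobicity(ctl.sequence), 2),
            })
    control_df = pd.DataFrame(control_rows, columns=[
        "pdb_id", "chain", "sequence", "length", "ss_string", "ss_category",
        "avg_sasa", "avg_hydropathy"])

    classifications = {pid: m.classification for pid, m in models.items()}
    summaries = _summaries(hit_df, control_df, hits, classifications)

    cham = classify.find_chameleons(
        [(row["_hit"], row["ss_category"]) for _, row in hit_df.iterrows()])
    summaries["chameleons"] = pd.DataFrame(
        [{"sequence": g.sequence,
          "n_occurrences": len(g.members),
          "categories": ",".join(sorted({c for _, c in g.members})),
          "is_chameleon": g.is_chameleon}
         for g in cham])

    hit_df = hit_df.drop(columns=["_hit"])
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hit_df.to_csv(out / "hits.tsv", sep="\t", index=False)
        control_df.to_csv(out / "controls.tsv", sep="\t", index=False)
        for name, df in summaries.items():
            df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
        pd.DataFrame(exclusions, columns=["pdb_id", "chain", "window",
                                          "reason"]).to_csv(
            out / "exclusions.tsv", sep="\t", index=False)
        if failures:
            pd.DataFrame(failures, columns=["path", "error"]).to_csv(
                out / "failures.tsv", sep="\t", index=False)
    return PipelineResult(hits=hit_df, controls=control_df,
                          summaries=summaries, exclusions=exclusions,
                          failures=failures)
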