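"""Configuration-driven chaining of annotation and filter stages.

Each stage reads its predecessor's per-individual VCFs and writes new ones,
so every intermediate is itself a valid, self-describing VCF: a provenance
header line (``##VK_STAGE=<index>:<name>:<hash>``) is appended per stage,
where the hash digests the stage name, its canonicalized parameters, the
digests of the resource files it consumes and the upstream hash.  Resume
walks the stage list, skips every stage whose recorded provenance matches
the expected hash, and re-runs from the first mismatch onwards.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import core_annotation as ca
from . import extended_annotation as ea
from . import inheritance as inh
from . import variant_filters as vf
from .gene_model import GeneMapParams, RegionMap, build_region_map, load_gene_map
from .vcf_io import (
    CHET_INFO_KEY,
    MODEL_INFO_KEY,
    Affection,
    Pedigree,
    Variant,
    VCFHeader,
    normalize_chrom,
    parse_pedigree,
    read_vcf,
    sort_variants,
    write_vcf,
)

PROVENANCE_PREFIX = "##VK_STAGE="


class ConfigError(Exception):
    pass


class PipelineError(Exception):
    pass


@dataclass
class StageSpec:
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    run_id: str
    pedigree: Path
    output_dir: Path
    stages: List[StageSpec]
    inputs: Optional[Dict[str, Path]] = None  # default: PED column 7
    genome: Optional[Path] = None
    gene_map: Optional[Path] = None
    aaf_table: Optional[Path] = None
    domain_table: Optional[Path] = None
    expression_table: Optional[Path] = None
    report: bool = True


_STAGE_NAMES = {
    "sort",
    "add_genes",
    "add_function",
    "add_zygosity",
    "physical_location",
    "novel",
    "read_depth",
    "call_quality",
    "mutation_type",
    "aaf",
    "same_variant",
    "same_gene",
    "inheritance",
    "isoform_context",
    "protein_context",
    "gene_expression",
}

#: stages that must run after the named annotators
_DEPS = {
    "add_function": {"add_genes"},
    "mutation_type": {"add_function"},
    "same_gene": {"add_genes"},
    "isoform_context": {"add_genes"},
    "protein_context": {"add_function"},
    "gene_expression": {"add_genes"},
}

_INHERITANCE_DEPS = {
    "AD": {"add_zygosity"},
    "AD_denovo": {"add_zygosity"},
    "XD": {"add_zygosity"},
    "AR": {"add_genes", "add_zygosity"},
    "XR": {"add_genes", "add_zygosity"},
    "mosaic": set(),
}

_STAGE_RESOURCES = {
    "add_genes": ("gene_map",),
    "add_function": ("genome",),
    "isoform_context": ("gene_map",),
    "protein_context": ("domain_table",),
    "gene_expression": ("expression_table",),
}


# ---------------------------------------------------------------------------
# config loading / validation

def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def p(key):
        v = raw.get(key)
        return (base / v) if v else None

    resources = raw.get("resources", {})

    def r(key):
        v = resources.get(key)
        return (base / v) if v else None

    inputs = raw.get("inputs")
    if inputs:
        inputs = {k: base / v for k, v in inputs.items()}
    stages = []
    for s in raw.get("stages", []):
        if "stage" not in s:
            raise ConfigError("every stage entry needs a 'stage' key")
        stages.append(StageSpec(name=s["stage"], params=s.get("params", {}) or {}))
    if not raw.get("pedigree"):
        raise ConfigError("config must name a pedigree file")
    return PipelineConfig(
        run_id=str(raw.get("run_id", "run")),
        pedigree=base / raw["pedigree"],
        output_dir=base / raw.get("output_dir", "run"),
        stages=stages,
        inputs=inputs,
        genome=r("genome"),
        gene_map=r("gene_map"),
        aaf_table=r("aaf_table"),
        domain_table=r("domain_table"),
        expression_table=r("expression_table"),
        report=bool(raw.get("report", True)),
    )


def validate_config(config: PipelineConfig, pedigree: Optional[Pedigree] = None) -> List[StageSpec]:
    """Check stage names, ordering constraints and pedigree requirements;
    return the ordered execution plan."""
    if pedigree is None:
        pedigree = parse_pedigree(config.pedigree)
    seen: set = set()
    n_inputs = len(_resolve_inputs(config, pedigree))
    for spec in config.stages:
        if spec.name not in _STAGE_NAMES:
            raise ConfigError(f"unknown stage {spec.name!r}")
        needed = set(_DEPS.get(spec.name, ()))
        if spec.name == "inheritance":
            model = spec.params.get("model")
            if model not in _INHERITANCE_DEPS:
                raise ConfigError(
                    f"inheritance stage needs a model among "
                    f"{sorted(_INHERITANCE_DEPS)}, got {model!r}"
                )
            needed |= _INHERITANCE_DEPS[model]
            if not pedigree.affected():
                raise ConfigError(
                    "inheritance filtering requires a pedigree with >=1 affected"
                )
        missing = needed - seen
        if missing:
            raise ConfigError(
                f"stage {spec.name!r} requires {sorted(missing)} to run first"
            )
        if spec.name in ("same_variant", "same_gene") and n_inputs < 2:
            raise ConfigError(f"stage {spec.name!r} needs >=2 case files")
        for res in _STAGE_RESOURCES.get(spec.name, ()):
            if getattr(config, res) is None:
                raise ConfigError(f"stage {spec.name!r} needs resource {res!r}")
        seen.add(spec.name)
    return list(config.stages)


def _resolve_inputs(config: PipelineConfig, pedigree: Pedigree) -> Dict[str, Path]:
    if config.inputs:
        return dict(config.inputs)
    inputs = {}
    base = Path(config.pedigree).parent
    for ind in pedigree.individuals:
        if ind.vcf_path:
            vp = Path(ind.vcf_path)
            inputs[ind.individual_id] = vp if vp.is_absolute() else base / vp
    if not inputs:
        raise ConfigError(
            "no input VCFs: provide 'inputs' or a 7th PED column with paths"
        )
    return inputs


# ---------------------------------------------------------------------------
# provenance

def _digest_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_hash(upstream: str, spec: StageSpec, resource_digests: List[str]) -> str:
    payload = json.dumps(
        {
            "upstream": upstream,
            "stage": spec.name,
            "params": spec.params,
            "resources": resource_digests,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance_line(index: int, spec: StageSpec, h: str) -> str:
    return f"{PROVENANCE_PREFIX}{index}:{spec.name}:{h}"


def _last_provenance(header: VCFHeader) -> Optional[str]:
    lines = header.provenance_lines()
    return lines[-1] if lines else None


# ---------------------------------------------------------------------------
# runner

@dataclass
class StageLog:
    index: int
    name: str
    executed: bool
    n_in: int
    n_out: int
    seconds: float


@dataclass
class RunResult:
    executed: List[str]
    skipped: List[str]
    log: List[StageLog]
    final_vcfs: Dict[str, Path]
    report_html: Optional[Path] = None
    report_tsv: Optional[Path] = None


class PipelineRunner:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.pedigree = parse_pedigree(config.pedigree)
        self.plan = validate_config(config, self.pedigree)
        self.inputs = _resolve_inputs(config, self.pedigree)
        self._region_map: Optional[RegionMap] = None
        self._region_map_token: Optional[str] = None
        self._genome: Optional[ca.GenomeSequence] = None
        self._transcripts = None

    # -- resource accessors ------------------------------------------------
    def genome(self) -> ca.GenomeSequence:
        if self._genome is None:
            if self.config.genome is None:
                raise PipelineError("config has no genome FASTA")
            self._genome = ca.GenomeSequence(self.config.genome)
        return self._genome

    def transcripts(self):
        if self._transcripts is None:
            if self.config.gene_map is None:
                raise PipelineError("config has no gene map")
            self._transcripts = load_gene_map(self.config.gene_map)
        return self._transcripts

    def region_map(self, params: GeneMapParams) -> RegionMap:
        token = params.cache_token()
        if self._region_map is None or self._region_map_token != token:
            self._region_map = build_region_map(self.transcripts(), params)
            self._region_map_token = token
        return self._region_map

    def chrom_order(self) -> List[str]:
        if self.config.genome is not None:
            return [normalize_chrom(c) for c in self.genome().chromosomes()]
        seen = []
        for ind, path in self.inputs.items():
            header, variants = read_vcf(path)
            for v in variants:
                c = normalize_chrom(v.chrom)
                if c not in seen:
                    seen.append(c)
        return seen

    # -- execution ---------------------------------------------------------
    def run(self, resume: bool = False) -> RunResult:
        outdir = Path(self.config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        headers: Dict[str, VCFHeader] = {}
        state: Dict[str, List[Variant]] = {}
        for ind, path in self.inputs.items():
            if not Path(path).exists():
                raise PipelineError(f"input VCF for {ind!r} not found: {path}")
            header, variants = read_vcf(path)
            headers[ind] = header
            state[ind] = variants
        upstream = hashlib.sha256()
        for ind in sorted(self.inputs):
            upstream.update(_digest_file(self.inputs[ind]).encode())
        upstream.update(_digest_file(self.config.pedigree).encode())
        upstream_hash = upstream.hexdigest()[:16]

        executed: List[str] = []
        skipped: List[str] = []
        log: List[StageLog] = []
        for index, spec in enumerate(self.plan, start=1):
            res_digests = [
                _digest_file(getattr(self.config, r))
                for r in _STAGE_RESOURCES.get(spec.name, ())
            ]
            h = _stage_hash(upstream_hash, spec, res_digests)
            stage_dir = outdir / f"stage_{index:02d}_{spec.name}"
            n_in = sum(len(v) for v in state.values())
            t0 = time.perf_counter()
            if resume and self._stage_complete(stage_dir, index, spec, h):
                headers, state = self._load_stage(stage_dir)
                skipped.append(spec.name)
                log.append(
                    StageLog(index, spec.name, False, n_in,
                             sum(len(v) for v in state.values()),
                             time.perf_counter() - t0)
                )
                upstream_hash = h
                continue
            try:
                state = self._apply_stage(spec, state, headers)
            except Exception as exc:
                raise PipelineError(
                    f"stage {index} ({spec.name}) failed: {exc}"
                ) from exc
            prov = _provenance_line(index, spec, h)
            stage_dir.mkdir(parents=True, exist_ok=True)
            for ind in self.inputs:
                header = headers[ind].copy()
                header.meta_lines.append(prov)
                write_vcf(header, state[ind], stage_dir / f"{ind}.vcf")
                headers[ind] = header
            executed.append(spec.name)
            log.append(
                StageLog(index, spec.name, True, n_in,
                         sum(len(v) for v in state.values()),
                         time.perf_counter() - t0)
            )
            upstream_hash = h

        self._write_log(outdir, log)
        result = RunResult(
            executed=executed,
            skipped=skipped,
            log=log,
            final_vcfs={ind: outdir / f"stage_{len(self.plan):02d}_{self.plan[-1].name}" / f"{ind}.vcf"
                        for ind in self.inputs} if self.plan else {},
        )
        if self.config.report:
            html, tsv = generate_report(
                state, headers, self.pedigree, outdir / "report.html", outdir / "report.tsv"
            )
            result.report_html = html
            result.report_tsv = tsv
        return result

    def _stage_complete(self, stage_dir: Path, index: int, spec: StageSpec, h: str) -> bool:
        expected = _provenance_line(index, spec, h)
        for ind in self.inputs:
            path = stage_dir / f"{ind}.vcf"
            if not path.exists():
                return False
            try:
                header, _ = read_vcf(path)
            except Exception:
                warnings.warn(
                    f"corrupted intermediate {path}; re-running from stage {index}",
                    stacklevel=2,
                )
                return False
            if _last_provenance(header) != expected:
                return False
        return True

    def _load_stage(self, stage_dir: Path):
        headers, state = {}, {}
        by_id = {tx.tx_id: tx for tx in (self.transcripts() if self.config.gene_map else [])}
        for ind in self.inputs:
            header, variants = read_vcf(stage_dir / f"{ind}.vcf")
            for v in variants:
                for ann in v.annotations:
                    ann.transcript = by_id.get(ann.tx_id)
            headers[ind] = header
            state[ind] = variants
        return headers, state

    # -- stage dispatch ----------------------------------------------------
    def _apply_stage(self, spec: StageSpec, state, headers):
        name, p = spec.name, spec.params
        if name == "sort":
            order = p.get("chrom_order") or self.chrom_order()
            return {i: sort_variants(vs, order) for i, vs in state.items()}
        if name == "add_genes":
            params = GeneMapParams(
                promoter_bp=int(p.get("promoter_bp", 500)),
                splice_bp=int(p.get("splice_bp", 5)),
                enabled_regions=frozenset(p["enabled_regions"])
                if p.get("enabled_regions")
                else GeneMapParams().enabled_regions,
            )
            rmap = self.region_map(params)
            keep = bool(p.get("keep_intergenic", False))
            return {
                i: ca.annotate_genes(vs, rmap, keep_intergenic=keep)
                for i, vs in state.items()
            }
        if name == "add_function":
            genome = self.genome()
            return {i: ca.annotate_functions(vs, genome) for i, vs in state.items()}
        if name == "add_zygosity":
            lo = float(p.get("lo", 0.15))
            hi = float(p.get("hi", 0.85))
            return {i: ca.add_zygosity(vs, lo, hi) for i, vs in state.items()}
        if name == "physical_location":
            if "bed" in p:
                regions = vf.GenomicRegionSet.from_bed(
                    Path(self.config.pedigree).parent / p["bed"]
                )
            else:
                regions = vf.GenomicRegionSet(
                    [(r["chrom"], r["start"], r["end"]) for r in p["regions"]]
                )
            mode = p.get("mode", "keep")
            return {
                i: vf.filter_physical_location(vs, regions, mode)
                for i, vs in state.items()
            }
        if name == "read_depth":
            return {
                i: vf.filter_read_depth(
                    vs, int(p.get("min_dp", 10)), p.get("scope", "any_sample")
                )
                for i, vs in state.items()
            }
        if name == "call_quality":
            return {
                i: vf.filter_call_quality(vs, float(p.get("min_qual", 20)))
                for i, vs in state.items()
            }
        if name == "mutation_type":
            return {
                i: vf.filter_mutation_type(vs, set(p["keep"])) for i, vs in state.items()
            }
        if name == "aaf":
            table = vf.AlleleFrequencyTable(self.config.aaf_table)
            return {
                i: vf.filter_aaf(
                    vs,
                    table,
                    float(p.get("max_af", 0.01)),
                    p.get("absent_policy", "keep"),
                )
                for i, vs in state.items()
            }
        if name == "novel":
            table = vf.AlleleFrequencyTable(self.config.aaf_table)
            return {
                i: vf.filter_novel(vs, table, p.get("mode", "keep_novel"))
                for i, vs in state.items()
            }
        if name == "same_variant":
            ids = sorted(state)
            filtered = vf.filter_same_variant([state[i] for i in ids])
            return dict(zip(ids, filtered))
        if name == "same_gene":
            ids = sorted(state)
            filtered = vf.filter_same_gene([state[i] for i in ids])
            return dict(zip(ids, filtered))
        if name == "inheritance":
            return self._inheritance_stage(p, state)
        if name == "isoform_context":
            return {
                i: ea.annotate_isoform_ids(vs, self.transcripts())
                for i, vs in state.items()
            }
        if name == "protein_context":
            table = ea.ProteinDomainTable.load(self.config.domain_table)
            return {
                i: ea.annotate_protein_domains(vs, table) for i, vs in state.items()
            }
        if name == "gene_expression":
            table = ea.ExpressionTable.load(self.config.expression_table)
            return {
                i: ea.filter_gene_expression(
                    vs,
                    table,
                    p["tissue"],
                    min_expr=p.get("min_expr"),
                    max_expr=p.get("max_expr"),
                )
                for i, vs in state.items()
            }
        raise ConfigError(f"unknown stage {name!r}")

    def _inheritance_stage(self, p: dict, state):
        model = p["model"]
        out = {i: [] for i in state}
        chet_tags: Dict[inh.Key, List[str]] = {}
        surviving: set = set()
        for fam in self.pedigree.families():
            fam_inputs = {
                m.individual_id: state[m.individual_id]
                for m in self.pedigree.members(fam)
                if m.individual_id in state
            }
            if not fam_inputs:
                continue
            if not self.pedigree.affected(fam):
                continue
            view = inh.FamilyGenotypeView.from_variants(self.pedigree, fam, fam_inputs)
            if model in ("AD", "AD_denovo"):
                keys = inh.filter_autosomal_dominant(
                    view,
                    de_novo=(model == "AD_denovo"),
                    incomplete_penetrance=bool(p.get("incomplete_penetrance", False)),
                )
            elif model == "AR":
                hom, chet = inh.filter_autosomal_recessive(view)
                keys = set(hom)
                for cg in chet:
                    for k in cg.keys:
                        keys.add(k)
                        chet_tags.setdefault(k, []).append(self._chet_tag(cg, k))
            elif model == "XD":
                xview = self._x_subview(view)
                keys = inh.filter_x_dominant(xview)
            elif model == "XR":
                xview = self._x_subview(view)
                hom, chet = inh.filter_x_recessive(xview)
                keys = set(hom)
                for cg in chet:
                    for k in cg.keys:
                        keys.add(k)
                        chet_tags.setdefault(k, []).append(self._chet_tag(cg, k))
            elif model == "mosaic":
                window = inh.MosaicWindow(
                    float(p.get("min_af", 0.10)), float(p.get("max_af", 0.35))
                )
                keys = inh.mosaic_keys(view, window)
            else:
                raise ConfigError(f"unknown inheritance model {model!r}")
            surviving |= keys
        for ind, variants in state.items():
            kept = []
            for v in variants:
                k = inh.variant_key(v)
                if k in surviving:
                    v.info[MODEL_INFO_KEY] = p["model"]
                    if k in chet_tags:
                        v.info[CHET_INFO_KEY] = "|".join(chet_tags[k])
                    kept.append(v)
            out[ind] = kept
        return out

    @staticmethod
    def _x_subview(view: inh.FamilyGenotypeView) -> inh.FamilyGenotypeView:
        xz = {k: v for k, v in view.zygosity.items() if inh.is_x(k[0])}
        xa = {k: v for k, v in view.alt_fraction.items() if inh.is_x(k[0])}
        xg = {k: v for k, v in view.genes_by_key.items() if inh.is_x(k[0])}
        return inh.FamilyGenotypeView(
            view.family_id,
            view.affected,
            view.unaffected,
            view.sex,
            view.parents,
            xz,
            xa,
            xg,
            view.genotyped,
        )

    @staticmethod
    def _chet_tag(cg: inh.CHetGene, key: inh.Key) -> str:
        partners = [k for k in cg.keys if k != key]
        enc = lambda k: f"{k[0]}_{k[1]}_{k[2]}_{k[3]}"
        return f"{cg.gene}:" + "+".join(enc(k) for k in partners)

    @staticmethod
    def _write_log(outdir: Path, log: List[StageLog]) -> None:
        with open(outdir / "run_log.tsv", "w") as fh:
            fh.write("index\tstage\texecuted\tn_in\tn_out\tseconds\n")
            for entry in log:
                fh.write(
                    f"{entry.index}\t{entry.name}\t{int(entry.executed)}\t"
                    f"{entry.n_in}\t{entry.n_out}\t{entry.seconds:.3f}\n"
                )


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunResult:
    return PipelineRunner(config).run(resume=resume)


def resume_pipeline(config: PipelineConfig) -> RunResult:
    return PipelineRunner(config).run(resume=True)


# ---------------------------------------------------------------------------
# report

_REPORT_COLUMNS = [
    "chromosome",
    "position",
    "rsID",
    "gene",
    "gene context",
    "cDNA change",
    "protein change",
    "functional change",
    "isoform",
    "domain",
    "inheritance",
]


def generate_report(
    state: Dict[str, List[Variant]],
    headers: Dict[str, VCFHeader],
    pedigree: Pedigree,
    out_html,
    out_tsv,
):
    """Consolidate all remaining variants into an HTML table and its TSV twin.

    One row per (variant, transcript annotation); zygosity cells for every
    case (affected) and control (unaffected) individual; sortable and
    searchable client-side (e.g. searching "REF" isolates reference-isoform
    rows).
    """
    cases = [i.individual_id for i in pedigree.individuals if i.affected is Affection.AFFECTED]
    controls = [i.individual_id for i in pedigree.individuals if i.affected is not Affection.AFFECTED]
    cases = [c for c in cases if c in state]
    controls = [c for c in controls if c in state]

    merged: Dict = {}
    order: List = []
    for ind, variants in state.items():
        for v in variants:
            k = inh.variant_key(v)
            if k not in merged:
                merged[k] = {"variant": v, "zyg": {}}
                order.append(k)
            z = next(iter(v.zygosity.values()), None)
            if z is not None:
                merged[k]["zyg"][ind] = z.value
            if len(v.annotations) > len(merged[k]["variant"].annotations):
                merged[k]["variant"] = v

    rows = []
    for k in sorted(order):
        entry = merged[k]
        v = entry["variant"]
        anns = v.annotations or [None]
        funcs = v.functional or [None] * len(anns)
        for ann, fn in zip(anns, funcs):
            row = {
                "chromosome": v.chrom,
                "position": v.pos,
                "rsID": v.id or ".",
                "gene": ann.gene if ann else ".",
                "gene context": ann.region if ann else ".",
                "cDNA change": (fn.cdna_change if fn else (ann.cdna if ann else ".")) or ".",
                "protein change": (fn.protein_change if fn else None) or ".",
                "functional change": (fn.mutation_type if fn else None) or ".",
                "isoform": (ann.iso_tag if ann else None) or ".",
                "domain": (ann.domain if ann else None) or ".",
                "inheritance": _inheritance_cell(v),
            }
            for c in cases:
                row[f"case:{c}"] = entry["zyg"].get(c, "HOM_REF")
            for c in controls:
                row[f"control:{c}"] = entry["zyg"].get(c, "HOM_REF")
            rows.append(row)

    columns = _REPORT_COLUMNS + [f"case:{c}" for c in cases] + [f"control:{c}" for c in controls]
    out_tsv = Path(out_tsv)
    with open(out_tsv, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")

    out_html = Path(out_html)
    out_html.write_text(_render_html(columns, rows))
    return out_html, out_tsv


def _inheritance_cell(v: Variant) -> str:
    parts = []
    if MODEL_INFO_KEY in v.info:
        parts.append(str(v.info[MODEL_INFO_KEY]))
    if CHET_INFO_KEY in v.info:
        parts.append(f"C-HET {v.info[CHET_INFO_KEY]}")
    return " ".join(parts) or "."


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Variant summary</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; }}
table {{ border-collapse: collapse; width: 100%; }}
th, td {{ border: 1px solid #ccc; padding: 4px 8px; font-size: 13px; }}
th {{ background: #eee; cursor: pointer; position: sticky; top: 0; }}
tr:nth-child(even) {{ background: #fafafa; }}
input {{ margin-bottom: 1em; padding: 4px; width: 24em; }}
</style></head><body>
<h2>Variant summary ({nrows} rows)</h2>
<input id="q" placeholder="search (e.g. missense, promoter_up, REF)" onkeyup="filt()">
<table id="t"><thead><tr>{header}</tr></thead><tbody>
{body}
</tbody></table>
<script>
function filt() {{
  var q = document.getElementById('q').value.toLowerCase();
  var rows = document.querySelectorAll('#t tbody tr');
  rows.forEach(function(r) {{
    r.style.display = r.textContent.toLowerCase().indexOf(q) >= 0 ? '' : 'none';
  }});
}}
var asc = {{}};
document.querySelectorAll('#t th').forEach(function(th, i) {{
  th.onclick = function() {{
    var tb = document.querySelector('#t tbody');
    var rows = Array.from(tb.rows);
    asc[i] = !asc[i];
    rows.sort(function(a, b) {{
      var x = a.cells[i].textContent, y = b.cells[i].textContent;
      var nx = parseFloat(x), ny = parseFloat(y);
      var c = (!isNaN(nx) && !isNaN(ny)) ? nx - ny : x.localeCompare(y);
      return asc[i] ? c : -c;
    }});
    rows.forEach(function(r) {{ tb.appendChild(r); }});
  }};
}});
</script></body></html>
"""


def _render_html(columns: List[str], rows: List[dict]) -> str:
    header = "".join(f"<th>{c}</th>" for c in columns)
    body_lines = []
    for row in rows:
        cells = "".join(f"<td>{row[c]}</td>" for c in columns)
        body_lines.append(f"<tr>{cells}</tr>")
    return _HTML_TEMPLATE.format(
        nrows=len(rows), header=header, body="\n".join(body_lines)
    )


# ---------------------------------------------------------------------------
# progression plot (variant counts per stage)

def plot_variant_progression(log: List[StageLog], path) -> Path:
    """Render the per-stage variant-count waterfall to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [f"{e.index}:{e.name}" for e in log]
    counts = [e.n_out for e in log]
    fig, ax = plt.subplots(figsize=(max(6, len(log) * 1.2), 4))
    ax.bar(range(len(log)), counts, color="#4477aa")
    ax.set_xticks(range(len(log)))
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("variants after stage (all files)")
    ax.set_yscale("symlog")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# ready-made configs for the simulated models

_SIM_MODEL_TO_STAGE = {
    "AD": "AD",
    "AD_denovo": "AD_denovo",
    "AR_HOM": "AR",
    "AR_CHET": "AR",
    "XLD": "XD",
    "XLR": "XR",
    "mosaic": "mosaic",
}


def default_model_config(model: str, directory) -> dict:
    """Config dict (relative paths) for a simulated family directory."""
    stage_model = _SIM_MODEL_TO_STAGE[model]
    return {
        "run_id": f"{model.lower()}_analysis",
        "pedigree": "family.ped",
        "output_dir": "run",
        "resources": {
            "genome": "genome.fa",
            "gene_map": "genes.refgene.tsv",
            "aaf_table": "af_table.tsv",
            "domain_table": "domains.tsv",
            "expression_table": "expression.tsv",
        },
        "stages": [
            {"stage": "sort"},
            {"stage": "add_genes", "params": {"promoter_bp": 500, "splice_bp": 5}},
            {"stage": "add_function"},
            {"stage": "add_zygosity"},
            {"stage": "inheritance", "params": {"model": stage_model}},
        ],
        "report": True,
    }


def write_config(config: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
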