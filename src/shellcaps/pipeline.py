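"""End-to-end orchestration: simulate -> pcr -> discover -> design -> genotype.

A run is driven by a single YAML config; the resolved config is serialised
next to the outputs so any run is reproducible from its artifacts alone.
Machine-readable outputs go only to files; logging goes to standard error
with stage-tagged lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import caps_design, digest_genotype, insilico_pcr, snp_effects
from .core_seq import NucSequence, read_fasta, write_fasta
from .errors import ConfigError, PipelineError
from .synthetic_cohort import (
    GeneratorConfig, default_marker_model, emit_cohort, make_alleles, make_panel,
)

log = logging.getLogger("shellcaps")

_GEN_FIELDS = {
    f.name for f in dataclasses.fields(GeneratorConfig)
    if f.name not in ("primer_pair", "enzyme", "flank_ssrs")
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    generator: dict = field(default_factory=dict)
    design: list[tuple[str, int]] = field(default_factory=lambda: [("DxP", 80), ("TxT", 60)])
    tolerance: int = 15
    window: int = 30
    enzymes_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        errors = []
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                errors.append(f"unknown field {key!r}")
        if "out_dir" not in raw:
            errors.append("missing required field 'out_dir'")
        gen = raw.get("generator", {})
        if not isinstance(gen, dict):
            errors.append("'generator' must be a mapping")
        else:
            for key in gen:
                if key not in _GEN_FIELDS:
                    errors.append(f"unknown generator field {key!r}")
        design = raw.get("design", [["DxP", 80], ["TxT", 60]])
        norm_design = []
        for item in design:
            try:
                cross, n = item
                norm_design.append((str(cross), int(n)))
            except (TypeError, ValueError):
                errors.append(f"bad design entry {item!r} (want [cross, n])")
        enz = raw.get("enzymes_path")
        if enz is not None and not Path(enz).exists():
            errors.append(f"enzymes_path {enz!r} does not exist")
        if errors:  # report every violation at once, not first-failure
            raise ConfigError(f"{path}: " + "; ".join(errors))
        cfg = cls(
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            generator=dict(gen),
            design=norm_design,
            tolerance=int(raw.get("tolerance", 15)),
            window=int(raw.get("window", 30)),
            enzymes_path=enz,
            log_level=str(raw.get("log_level", "INFO")),
        )
        if seed is not None:
            cfg.seed = seed
        return cfg

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the artifact manifest (also written to disk).

    A failing stage halts the run with a :class:`PipelineError` naming it.
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="[%(name)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gcfg = config.generator_config()
    manifest: list[dict] = []

    def record(stage: str, path: str | Path) -> None:
        p = Path(path)
        manifest.append({"stage": stage, "file": p.name, "sha256": _sha256(p)})

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        paths = emit_cohort(gcfg, config.design, out)
        cut, uncut = make_alleles(gcfg)
        write_fasta([cut, uncut], out / "alleles.fa")
        resolved = dataclasses.asdict(config)
        (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved))
        for p in (*paths.values(), out / "alleles.fa", out / "config.resolved.yaml"):
            record("simulate", p)
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("pcr")
        templates = read_fasta(paths["templates"])
        amplicons = []
        for t in templates:
            prods = insilico_pcr.amplify(t, gcfg.primer_pair)
            if len(prods) != 1:
                raise PipelineError(
                    f"template {t.id}: expected exactly one product, got {len(prods)}"
                )
            a = prods[0]
            amplicons.append(NucSequence(t.id.removesuffix("_template"), a.seq,
                                         f"amplicon {a.start}-{a.end}"))
        write_fasta(amplicons, out / "amplicons.fa")
        record("pcr", out / "amplicons.fa")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'pcr' failed: {exc}") from exc

    try:
        stage("discover-snps")
        panel = make_panel(gcfg)
        cols = snp_effects.classify_variants(panel)
        with open(out / "variants.tsv", "w") as fh:
            fh.write("column\tclassification\tti_tv\tcarrier\talleles\n")
            for c in cols:
                alleles = ",".join(f"{k}:{v}" for k, v in sorted(c.alleles.items()))
                fh.write(f"{c.column}\t{c.classification}\t{c.ti_tv}"
                         f"\t{c.carrier or '-'}\t{alleles}\n")
        record("discover-snps", out / "variants.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'discover-snps' failed: {exc}") from exc

    try:
        stage("design-caps")
        enzymes = caps_design.load_enzymes(config.enzymes_path)
        cands = caps_design.find_caps_candidates(cut, uncut, enzymes, config.window)
        ranked = caps_design.rank_candidates(cands)
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("enzyme\tdifferential\tnear_variants\tfragments_a"
                     "\tfragments_b\tseparation\n")
            for c in ranked:
                fh.write(f"{c.enzyme.name}\t{c.differential}"
                         f"\t{','.join(map(str, c.variant_positions))}"
                         f"\t{','.join(map(str, c.fragments_a))}"
                         f"\t{','.join(map(str, c.fragments_b))}\t{c.separation}\n")
        record("design-caps", out / "candidates.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'design-caps' failed: {exc}") from exc

    try:
        stage("genotype")
        model = default_marker_model(gcfg)
        amp_by_id = {a.id: a.seq for a in amplicons}
        sheet_rows = [
            line.split("\t") for line in
            Path(paths["samples"]).read_text().strip().splitlines()[1:]
        ]
        with open(out / "calls.tsv", "w") as fh_calls, \
                open(out / "segregation.tsv", "w") as fh_seg:
            fh_calls.write("sample_id\tcross\tcall\n")
            fh_seg.write("cross\tn\tcounts\tchi_square\tdof\tp_value"
                         "\tcontamination\n")
            for cross in dict.fromkeys(r[3] for r in sheet_rows):
                samples = [
                    (r[0], (amp_by_id[r[1]], amp_by_id[r[2]]))
                    for r in sheet_rows if r[3] == cross
                ]
                res = digest_genotype.screen_cohort(
                    samples, model, cross, config.tolerance
                )
                for sid, call in res.calls.items():
                    fh_calls.write(f"{sid}\t{cross}\t{call}\n")
                counts = ",".join(f"{k}:{v}" for k, v in sorted(res.counts.items()))
                fh_seg.write(f"{cross}\t{len(samples)}\t{counts}"
                             f"\t{res.chi_square:.4f}\t{res.dof}\t{res.p_value:.4g}"
                             f"\t{len(res.contamination)}\n")
        record("genotype", out / "calls.tsv")
        record("genotype", out / "segregation.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'genotype' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d artifacts to %s", len(manifest), out)
    return {"out_dir": str(out), "artifacts": manifest}
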