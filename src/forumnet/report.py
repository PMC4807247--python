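"""End-to-end pipeline orchestration.

``run_all`` takes a :class:`RunConfig` (typically parsed from YAML),
builds or loads the corpus, computes the linguistic summaries, the
conversation network and its metric row, the requested null-model rows,
the Bow-Tie table, the member feature table and its Spearman matrix, and
writes everything as delimited/JSON files stamped with the configuration
and seeds. Deterministic for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bowtie as bowtie_mod
from . import corpus as corpus_mod
from . import integrate as integrate_mod
from . import lexicon as lexicon_mod
from . import netbuild, netmetrics, nullmodels

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    corpus_path: str | None = None  # one of corpus_path / generator
    generator: dict | None = None  # GeneratorParams overrides
    lexicon_path: str | None = None  # default: shipped toy lexicon
    models: list[dict] = field(default_factory=list)  # ModelSpec kwargs
    out_dir: str = "forumnet_out"
    seed: int = 0
    fit_power_laws: bool = True

    def validate(self) -> None:
        if (self.corpus_path is None) == (self.generator is None):
            raise ValueError("configure exactly one of corpus_path or generator")
        if self.corpus_path is not None and not Path(self.corpus_path).exists():
            raise FileNotFoundError(self.corpus_path)
        if self.lexicon_path is not None and not Path(self.lexicon_path).exists():
            raise FileNotFoundError(self.lexicon_path)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns {artifact name: file path}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # --- corpus ---
    if config.generator is not None:
        params = corpus_mod.GeneratorParams(**{"seed": config.seed, **config.generator})
        corpus = _stage("generate_corpus")(corpus_mod.generate_corpus, params)
    else:
        corpus = _stage("read_corpus")(corpus_mod.read_corpus, config.corpus_path)
    summary = corpus_mod.corpus_summary(corpus)
    p = out / "corpus_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    save("corpus_summary", p)

    # --- linguistics ---
    lex = (
        lexicon_mod.load_lexicon(config.lexicon_path)
        if config.lexicon_path
        else lexicon_mod.builtin_toy_lexicon()
    )
    profiles = _stage("member_profiles")(lexicon_mod.member_profiles, corpus, lex)
    prof_rows = {
        m: {"word_count": pr.word_count, "tag_rate": pr.tag_rate, **pr.rates}
        for m, pr in profiles.items()
    }
    prof_df = pd.DataFrame.from_dict(prof_rows, orient="index").sort_index()
    p = out / "member_profiles.csv"
    prof_df.to_csv(p, index_label="member")
    save("member_profiles", p)

    ling_summary = {
        "corpus_tag_rate_pct": lexicon_mod.corpus_tag_rate(corpus, lex),
        "affect_subgroups_pct": lexicon_mod.affect_subgroups(profiles.values()),
        "n_members_with_text": len(profiles),
    }
    p = out / "linguistic_summary.json"
    p.write_text(json.dumps(ling_summary, indent=2))
    save("linguistic_summary", p)

    freq = lexicon_mod.word_frequencies(corpus)
    p = out / "word_frequencies.csv"
    freq.to_csv(p, index=False)
    save("word_frequencies", p)

    # --- network ---
    graph = _stage("build_conversation_graph")(
        netbuild.build_conversation_graph, corpus
    )
    stripped = netbuild.strip_self_loops(graph)
    friend = netbuild.to_friend_graph(graph)
    rows = [
        netmetrics.network_summary(
            stripped, "conversation", fit_degrees=config.fit_power_laws
        ),
        netmetrics.network_summary(friend, "friend", fit_degrees=config.fit_power_laws),
    ]
    decomps = {"conversation": bowtie_mod.bowtie_decompose(stripped)}

    for i, mkw in enumerate(config.models):
        spec = nullmodels.ModelSpec(**{"seed": config.seed + i, **mkw})
        g = _stage(f"model:{spec.model}")(nullmodels.make_model, spec)
        rows.append(
            netmetrics.network_summary(
                g, spec.model, fit_degrees=config.fit_power_laws
            )
        )
        if g.is_directed():
            decomps[spec.model] = bowtie_mod.bowtie_decompose(g)

    metric_df = pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("name")
    metric_df["notes"] = metric_df["notes"].map(json.dumps)
    p = out / "network_summary.csv"
    metric_df.to_csv(p)
    save("network_summary", p)

    bt = bowtie_mod.bowtie_table(decomps)
    p = out / "bowtie.csv"
    bt.to_csv(p, index_label="class")
    save("bowtie", p)

    # --- integration ---
    table = _stage("member_feature_table")(
        integrate_mod.member_feature_table, corpus, graph, lex
    )
    p = out / "member_features.csv"
    table.to_csv(p, index_label="member")
    save("member_features", p)
    corr, npairs = integrate_mod.spearman_matrix(table)
    corr.to_csv(out / "spearman.csv")
    npairs.to_csv(out / "spearman_n.csv")
    save("spearman", str(out / "spearman.csv"))

    try:
        cmp_rec = integrate_mod.affect_comparison(table)
        p = out / "affect_comparison.json"
        p.write_text(json.dumps(dataclasses.asdict(cmp_rec), indent=2))
        save("affect_comparison", p)
    except ValueError:
        pass  # tiny corpora may lack members using both polarities

    stamp = {
        "config": dataclasses.asdict(config),
        "conventions": rows[0].notes,
        "self_loops": netbuild.self_loop_census(graph),
    }
    p = out / "run_manifest.json"
    p.write_text(json.dumps(stamp, indent=2))
    save("run_manifest", p)
    return artifacts
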