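#!/usr/bin/env python
"""Generate the synthetic knowledge graph and study cohort and write TSVs.

Produces results/data/: the typed node/edge lists, the concept→node mapping,
and timestamped patient event tables for a 200 + 200 case/control cohort with
planted prodromal signal, plus a short structural summary on stdout.
"""

from pathlib import Path

from kgprodromal import synth
from kgprodromal.kg import save_graph
from kgprodromal.records import write_event_tables

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    world = synth.generate_kg(synth.SyntheticKGSpec(seed=SEED))
    gen = synth.generate_cohort(
        synth.SyntheticCohortSpec(n_cases=200, n_controls=200, seed=SEED + 1), world)

    OUT.mkdir(parents=True, exist_ok=True)
    save_graph(world.kg, OUT / "nodes.tsv", OUT / "edges.tsv")
    write_event_tables(gen.records, OUT, labels=gen.labels)
    with open(OUT / "mapping.tsv", "w") as fh:
        fh.write("concept_id\tnode_id\n")
        for c in world.mapping.concepts:
            fh.write(f"{c}\t{world.mapping[c]}\n")

    n_events = sum(len(r.events) for r in gen.records)
    print(f"graph: {world.kg.n_nodes} nodes, {len(world.kg.edges)} edges; "
          f"target disease {world.target_disease} with "
          f"{len(world.prodromal_concepts)} prodromal entry concepts")
    print(f"cohort: {len(gen.records)} patients, {n_events} events "
          f"({n_events / len(gen.records):.1f} per patient)")
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
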