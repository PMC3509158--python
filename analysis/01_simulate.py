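"""Generate the synthetic fallow survey used by the downstream analyses.

Writes the five input tables (survey, traits, soils, infiltration curves,
plot metadata) for 18 grazed + 21 improved fallows to
``results/synthetic_data/``.
"""

import logging

import fallowfun as ff
from fallowfun import io

logging.basicConfig(level=logging.ERROR)

OUT = "results/synthetic_data"
SEED = 42


def main() -> None:
    cfg = ff.GeneratorConfig(seed=SEED)
    dataset = ff.generate_fallow_survey(cfg)
    io.write_dataset(dataset, OUT)
    counts = dataset.plots["fallow_type"].value_counts()
    print(f"wrote {len(dataset.plots)} fallows to {OUT}/ "
          f"({counts['grazed']} grazed, {counts['improved']} improved; seed {SEED})")
    print(f"species pool: {len(dataset.traits)}; "
          f"survey records: {len(dataset.survey)}; "
          f"infiltration points: {len(dataset.infiltration)}")


if __name__ == "__main__":
    main()
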