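"""Physiological rates from the steady-state chemostat records: specific
glucose/amino-acid uptake, ethanol secretion, product yield and productivity,
and the exchange-rate tables the enzyme-constrained model consumes."""

import argparse
from pathlib import Path

import pandas as pd

import omniflux as om
from omniflux import io

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--inputs", type=Path, default=Path("results/01_simulated"))
parser.add_argument("--out", type=Path, default=Path("results/05_rates"))
parser.add_argument("--product-mw-kda", type=float, default=54.4)
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

records = io.read_chemostat_csv(args.inputs / "chemostat.csv")
rows = []
for rec in records:
    y, prod = om.product_yield_and_productivity(rec)
    rates = om.rates_table(rec, {
        "glucose": ("EX_glc", "uptake"),
        "amino_acids": ("EX_aa", "uptake"),
        "ethanol": ("EX_etoh", "secretion"),
    })
    rates = pd.concat([rates, pd.DataFrame([{
        "reaction_id": "EX_amy", "rate": prod / args.product_mw_kda,
        "direction": "secretion"}])], ignore_index=True)
    io.write_frame_tsv(rates, args.out / f"rates_{rec.strain}_{rec.dilution_rate:g}.tsv")
    rows.append({"strain": rec.strain, "dilution_rate": rec.dilution_rate,
                 "q_glc": rates.loc[0, "rate"], "q_aa": rates.loc[1, "rate"],
                 "yield_mg_per_gdcw": y, "productivity_mg_per_gdcw_h": prod})
    print(f"{rec.strain} D={rec.dilution_rate:g}/h: glucose uptake "
          f"{rates.loc[0, 'rate']:.3f}, amino-acid uptake {rates.loc[1, 'rate']:.3f} "
          f"mmol/gDCW/h; yield {y:.1f} mg/gDCW, productivity {prod:.2f} mg/gDCW/h")
io.write_frame_tsv(pd.DataFrame(rows), args.out / "physiology.tsv")
print(f"outputs in {args.out}")
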