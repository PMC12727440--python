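"""Worked example of the exclusion-ledger arithmetic at full study scale.

A 14-profile x 10-control study (140 simulated sets, 420 images) with
scripted failures: two profiles whose simulation fails outright, and six
sets of one large-lesion profile whose lesioned image fails parcellation on
both attempts.  The ledger must conserve every set through the stages, and
removing two further outlier sets at the metric stage leaves 112 pairs for
the group comparison (111 degrees of freedom).

Writes results/exclusion_ledger_example.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS

from lesionbench.stats import SetStatus, compile_ledger

IMAGE_TYPES = ("lesion_free", "lesioned", "filled")


def scripted_records():
    records = []
    for i in range(1, 15):
        tbi = f"P{i:02d}"
        for j in range(1, 11):
            sim_ok = tbi not in ("P03", "P13")
            parc = {}
            if sim_ok:
                parc = {t: {"attempts": 1, "ok": True} for t in IMAGE_TYPES}
                if tbi == "P05" and j <= 6:
                    parc["lesioned"] = {"attempts": 2, "ok": False}
            records.append(SetStatus(
                set_id=f"{tbi}xHC{j:02d}", tbi_id=tbi, hc_id=f"HC{j:02d}",
                simulation_ok=sim_ok, parcellation=parc,
            ))
    return records


def main() -> None:
    records = scripted_records()
    ledger = compile_ledger(records)
    for r in ledger.sets_after_parcellation[:2]:
        r.outlier = True  # two sets flagged by the 1.5xIQR screen
    ledger = compile_ledger(records)
    counts = ledger.counts()
    print(json.dumps(counts, indent=2))
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "exclusion_ledger_example.json"
    out.write_text(json.dumps(ledger.to_dict()["counts"], indent=2))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
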