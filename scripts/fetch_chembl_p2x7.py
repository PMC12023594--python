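#!/usr/bin/env python
"""Optional convenience script: download the P2X7 LO dataset from ChEMBL.

Fetches IC50 activities for target CHEMBL4805 restricted to the four
documents of a published GSK lead-optimisation programme and writes a CSV
(id, smiles, pic50) suitable for ``rgcore run``. Requires network access;
nothing in the package or its tests depends on this script, and ChEMBL
curation changes can shift the record counts between database versions.

Usage:
    python scripts/fetch_chembl_p2x7.py --out p2x7.csv
"""

from __future__ import annotations

import argparse
import csv
import json
import math
import urllib.parse
import urllib.request

TARGET = "CHEMBL4805"
DOCUMENTS = ["CHEMBL1157114", "CHEMBL1221272", "CHEMBL1268987", "CHEMBL2218064"]
BASE = "https://www.ebi.ac.uk/chembl/api/data/activity.json"


def fetch_document(doc_id: str):
    rows = []
    params = {
        "target_chembl_id": TARGET,
        "document_chembl_id": doc_id,
        "standard_type": "IC50",
        "limit": 1000,
    }
    url = f"{BASE}?{urllib.parse.urlencode(params)}"
    while url:
        with urllib.request.urlopen(url, timeout=60) as resp:
            page = json.load(resp)
        for act in page.get("activities", []):
            smiles = act.get("canonical_smiles")
            value = act.get("standard_value")
            units = act.get("standard_units")
            if not smiles or value is None or units != "nM":
                continue
            nm = float(value)
            if nm <= 0:
                continue
            rows.append(
                {
                    "id": act["molecule_chembl_id"],
                    "smiles": smiles,
                    "pic50": round(-math.log10(nm * 1e-9), 4),
                }
            )
        nxt = page.get("page_meta", {}).get("next")
        url = f"https://www.ebi.ac.uk{nxt}" if nxt else None
    return rows


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="p2x7.csv")
    args = parser.parse_args()

    rows = []
    for doc in DOCUMENTS:
        got = fetch_document(doc)
        print(f"{doc}: {len(got)} activity records")
        rows.extend(got)

    with open(args.out, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "smiles", "pic50"])
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {len(rows)} records to {args.out}")


if __name__ == "__main__":
    main()
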