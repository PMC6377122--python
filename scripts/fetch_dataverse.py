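"""Download the original zebrafish VMR dataset (optional, needs network).

The recordings this package's models were designed for are deposited at
Harvard Dataverse, DOI 10.7910/DVN/HTXXKW. Nothing in the package or its
tests requires them; they are useful only for validating the normalization
on the real data. This script fetches the dataset listing via the
Dataverse API and downloads every file into a target directory.

Usage:
    python scripts/fetch_dataverse.py --out scratch/dataverse
"""

from __future__ import annotations

import argparse
import json
import urllib.request
from pathlib import Path

DOI = "doi:10.7910/DVN/HTXXKW"
API = "https://dataverse.harvard.edu/api"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    listing_url = (f"{API}/datasets/:persistentId/versions/:latest/files"
                   f"?persistentId={DOI}")
    with urllib.request.urlopen(listing_url) as resp:
        files = json.load(resp)["data"]
    print(f"{len(files)} files in {DOI}")
    for entry in files:
        df = entry["dataFile"]
        file_id, name = df["id"], df["filename"]
        dest = args.out / name
        if dest.exists():
            print(f"  {name}: already present")
            continue
        url = f"{API}/access/datafile/{file_id}?format=original"
        print(f"  downloading {name} ...")
        urllib.request.urlretrieve(url, dest)
    print(f"done -> {args.out}")


if __name__ == "__main__":
    main()
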