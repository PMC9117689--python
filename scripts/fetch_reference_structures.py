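"""Fetch and trim the two deposited receptor structures used by the
worked-example collective-variable checks.

Downloads the PDB entries for the antagonist-bound (inactive-like) and
agonist-bound (active-like) receptor, keeps only Cα ATOM records, and writes
them to tests/data/{5ung,6jod}_ca.pdb (a few tens of kilobytes each).
Needs network access; run once before the acceptance suite.
"""

from pathlib import Path
from urllib.request import urlopen

ACCESSIONS = ("5UNG", "6JOD")
OUT_DIR = Path(__file__).resolve().parent.parent / "tests" / "data"


def trim_ca(pdb_text: str) -> str:
    kept = []
    for line in pdb_text.splitlines():
        if line.startswith("ATOM") and line[12:16].strip() == "CA":
            kept.append(line)
        elif line.startswith(("HEADER", "TITLE", "END")):
            kept.append(line)
    return "\n".join(kept) + "\n"


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        url = f"https://files.rcsb.org/download/{acc}.pdb"
        print(f"fetching {url} ...")
        text = urlopen(url, timeout=60).read().decode()
        out = OUT_DIR / f"{acc.lower()}_ca.pdb"
        out.write_text(trim_ca(text))
        print(f"wrote {out} ({out.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
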