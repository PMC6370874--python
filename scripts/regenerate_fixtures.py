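"""Rewrite the packaged toy-genome fixtures from the deterministic builder.

Usage: python scripts/regenerate_fixtures.py
"""

from pathlib import Path

from ameloseq.toygenome import build_toy_genome, write_fixtures


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "ameloseq" / "data"
    toy = build_toy_genome()
    write_fixtures(toy, data_dir)
    print(f"wrote toy genome fixtures to {data_dir}")
    for chrom, seq in toy.genome.items():
        print(f"  {chrom}: {len(seq)} bp")
    print(f"  {len(toy.transcripts)} transcripts, {len(toy.targets)} targets")


if __name__ == "__main__":
    main()
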