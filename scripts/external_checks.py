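#!/usr/bin/env python
"""Optional geometry checks against deposited integrative models.

These checks require structure files downloaded from ModelArchive
(accessions ma-blbmg, ma-k9i3k, ma-89py8, ma-6cl90, ma-pdzpq) and are
therefore not part of the offline test suite. Given local copies, they
measure:

  * the Cα–Cα distance between Rpb1 K1268 and the terminal glycine of the
    transferred ubiquitin on the ubiquitination-competent model
    (expected ≈ 8.7 Å; ≈ 25.6 Å without ELOF1),
  * the buried-surface fraction of the STK19 chain in the assembled complex
    (expected > 0.80), and
  * the kink angle of the duplex DNA flanking STK19 (expected ≈ 140°).

Chain identifiers and residue numbers vary between depositions; pass the
ones used by your copy of the model.

Example:
    python scripts/external_checks.py distance ma-k9i3k.pdb A:1268:CA U:76:CA
    python scripts/external_checks.py buried ma-blbmg.pdb S
    python scripts/external_checks.py kink ma-blbmg.pdb D:1-12 D:13-24
"""

from __future__ import annotations

import argparse

from trajnet.geometry import buried_fraction, duplex_kink_angle, pair_distance
from trajnet.io import read_structure


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    sub = parser.add_subparsers(dest="command", required=True)

    d = sub.add_parser("distance", help="Cα–Cα distance between two selections")
    d.add_argument("model")
    d.add_argument("sel_a", help="chain:resnum:atom, e.g. A:1268:CA")
    d.add_argument("sel_b", help="chain:resnum:atom, e.g. U:76:CA")

    b = sub.add_parser("buried", help="buried-surface fraction of a chain")
    b.add_argument("model")
    b.add_argument("chain")

    k = sub.add_parser("kink", help="duplex kink angle between two arms")
    k.add_argument("model")
    k.add_argument("arm_a", help="chain:first-last, e.g. D:1-12")
    k.add_argument("arm_b", help="chain:first-last, e.g. D:13-24")

    args = parser.parse_args()
    model = read_structure(args.model)

    if args.command == "distance":
        dist = pair_distance(model, args.sel_a, args.sel_b)
        print(f"distance = {dist:.1f} A")
    elif args.command == "buried":
        result = buried_fraction(model, {args.chain})
        print(f"buried fraction of chain {args.chain} = {result.fraction:.3f}")
        for partner, share in sorted(
            result.partner_shares.items(), key=lambda kv: -kv[1]
        ):
            print(f"  partner {partner}: share {share:.3f}")
    elif args.command == "kink":
        arms = []
        for spec in (args.arm_a, args.arm_b):
            chain, rng = spec.split(":")
            lo, hi = rng.split("-")
            arms.append([(chain, r) for r in range(int(lo), int(hi) + 1)])
        angle = duplex_kink_angle(model, arms[0], arms[1])
        print(f"kink angle = {angle:.1f} degrees")


if __name__ == "__main__":
    main()
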