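"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (nested loops, base-by-base walks,
codon-by-codon translation) and shares no code with the package paths it
checks.
"""

from __future__ import annotations


def introns_of(exons):
    return [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]


def bruteforce_events(transcripts):
    """All AS events among a gene's transcripts as canonical descriptors.

    Compares every ordered pair of exon chains intron-by-intron:

    - ES: one chain keeps an internal exon whose two flanking introns are
      replaced by a single spanning intron in the other chain.
    - MXE: both chains keep exactly one (different, non-overlapping) internal
      exon between the same outer intron boundaries.
    - A5SS/A3SS: two introns share one boundary and the overlapping exon
      variants differ at the other (type depends on strand).
    - IR: an intron of one chain lies strictly inside an exon of the other.
    """
    found = set()
    for ta in transcripts:
        for tb in transcripts:
            if ta is tb:
                continue
            strand = ta.strand
            ia, ib = introns_of(ta.exons), introns_of(tb.exons)
            # ES and MXE: loop over internal exons of ta
            for i in range(1, len(ta.exons) - 1):
                x = ta.exons[i]
                s = ta.exons[i - 1][1] + 1
                e = ta.exons[i + 1][0] - 1
                if (s, e) in ib and x not in tb.exons:
                    found.add(("ES", x, (s, e)))
                for j in range(1, len(tb.exons) - 1):
                    y = tb.exons[j]
                    sb = tb.exons[j - 1][1] + 1
                    eb = tb.exons[j + 1][0] - 1
                    if (
                        (sb, eb) == (s, e)
                        and x != y
                        and (x[1] < y[0] or y[1] < x[0])
                        and x not in tb.exons
                        and y not in ta.exons
                    ):
                        a, b = sorted((x, y))
                        found.add(("MXE", a, b, (s, e)))
            # alternative splice sites
            for (s1, e1) in ia:
                for (s2, e2) in ib:
                    if e1 == e2 and s1 != s2:
                        la = [x for x in ta.exons if x[1] == s1 - 1]
                        lb = [x for x in tb.exons if x[1] == s2 - 1]
                        if la and lb and la[0][0] <= lb[0][1] and lb[0][0] <= la[0][1]:
                            long_e, short_e = (la[0], lb[0]) if la[0][1] > lb[0][1] else (lb[0], la[0])
                            etype = "A5SS" if strand == "+" else "A3SS"
                            found.add((etype, long_e, short_e, ("end", e1)))
                    if s1 == s2 and e1 != e2:
                        ra = [x for x in ta.exons if x[0] == e1 + 1]
                        rb = [x for x in tb.exons if x[0] == e2 + 1]
                        if ra and rb and ra[0][0] <= rb[0][1] and rb[0][0] <= ra[0][1]:
                            long_e, short_e = (ra[0], rb[0]) if ra[0][0] < rb[0][0] else (rb[0], ra[0])
                            etype = "A3SS" if strand == "+" else "A5SS"
                            found.add((etype, long_e, short_e, ("start", s1)))
            # intron retention: intron of tb strictly inside an exon of ta
            for (s, e) in ib:
                for x in ta.exons:
                    if x[0] < s and e < x[1]:
                        found.add(("IR", (s, e)))
    return found


def event_descriptor(ev):
    """Canonical descriptor of an AsEvent, matching bruteforce_events output."""
    c = ev.coord_map
    if ev.etype == "ES":
        return ("ES", c["skipped"], ev.span)
    if ev.etype == "MXE":
        return ("MXE", c["exon1"], c["exon2"], ev.span)
    if ev.etype == "IR":
        return ("IR", c["intron"])
    # A5SS/A3SS: shared boundary read off the junction keys
    def parse(key):
        rng = key.split(":")[1]
        s, e = rng.split("-")
        return int(s), int(e)

    (si, ei) = parse(ev.inclusion_junctions[0])
    (ss, es) = parse(ev.skipping_junctions[0])
    boundary = ("end", ei) if ei == es else ("start", si)
    return (ev.etype, c["long_exon"], c["short_exon"], boundary)


def tx_coord_walk(exons, strand, gpos):
    """Base-by-base transcript coordinate of a genomic position."""
    order = exons if strand == "+" else list(reversed(exons))
    coord = 0
    for s, e in order:
        rng = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        for g in rng:
            coord += 1
            if g == gpos:
                return coord
    raise ValueError("not exonic")


STOPS = {"TAA", "TAG", "TGA"}


def manual_orf_scan(exon_seqs, cds_start):
    """First stop codon by manual translation of a spliced sequence.

    ``exon_seqs`` are the altered transcript's exon sequences 5'->3'.
    Returns (stop_position_1based or None, last_junction_position).
    """
    seq = "".join(exon_seqs)
    stop = None
    i = cds_start - 1
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOPS:
            stop = i + 1
            break
        i += 3
    last_junction = sum(len(s) for s in exon_seqs[:-1])
    return stop, last_junction
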