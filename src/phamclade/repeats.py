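"""Repeated intergenic promoter-like elements and sigma70 motif scanning.

Elements of ~41 nt repeated in the spacers between ORFs are found by exact
15-mer seeding within intergenic sequence (both strands), seed merging into
instances, transitive clustering of instances sharing seeds, and fixed-length
(ungapped) refinement against a cluster representative.  Their per-position
conservation is summarised by a consensus profile, and a sliding mismatch
scan locates sigma70 promoter boxes (TTGACA ... TATAAT with a 15-19 nt
spacer) inside them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeRecord, extract_intergenic, reverse_complement

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"


@dataclass
class RepeatCluster:
    cluster_id: str
    instances: list[tuple[str, int, int, str, str]]  # (genome, start, end, strand, sequence)
    element_length: int

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def representative(self) -> str:
        return max((inst[4] for inst in self.instances), key=len)


@dataclass
class ConsensusProfile:
    counts: dict[str, list[int]]  # base -> per-position counts
    consensus: str  # majority base, lowercase where not fully conserved
    strictly_conserved_count: int

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class Sigma70Hit:
    genome_id: str
    start: int  # forward-strand coordinate of the leftmost promoter base
    strand: str
    minus35: str
    spacer_length: int
    minus10: str
    mismatches: tuple[int, int]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _identity_at_offset(a: str, b: str, offset: int) -> float:
    """Fraction identical over the overlap of b placed at ``offset`` in a."""
    start_a = max(0, offset)
    start_b = max(0, -offset)
    n = min(len(a) - start_a, len(b) - start_b)
    if n <= 0:
        return 0.0
    same = sum(a[start_a + i] == b[start_b + i] for i in range(n))
    return same / max(len(a), len(b))


def _best_offset(a: str, b: str, max_shift: int = 5) -> tuple[int, float]:
    best = (0, -1.0)
    for off in range(-max_shift, max_shift + 1):
        ident = _identity_at_offset(a, b, off)
        if ident > best[1]:
            best = (off, ident)
    return best


def find_intergenic_repeats(
    genome: GenomeRecord,
    min_len: int = 40,
    min_copies: int = 2,
    min_identity: float = 0.8,
    k: int = 15,
    whole_genome: bool = False,
) -> list[RepeatCluster]:
    """Repeated elements (>= min_len nt, >= min_copies instances at
    >= min_identity) in the intergenic regions of one genome.

    Repeats are searched in intergenic sequence only by default; the elements
    of interest are intergenic promoter motifs and the flag avoids CDS-level
    false positives.  ``whole_genome=True`` widens the search.
    """
    if whole_genome:
        regions = [(0, len(genome), genome.sequence)]
    else:
        regions = extract_intergenic(genome, min_len=k)

    # exact k-mer seeds, canonical over strands
    occurrences: dict[str, list[tuple[int, str]]] = {}
    for start, _end, seq in regions:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = reverse_complement(kmer)
            canon, strand = (kmer, "+") if kmer <= rc else (rc, "-")
            occurrences.setdefault(canon, []).append((start + i, strand))
    repeated = {km: occ for km, occ in occurrences.items() if len(set(p for p, _ in occ)) >= 2}

    # merge nearby seed positions into instance intervals
    seeds = sorted(
        {(pos, strand, km) for km, occ in repeated.items() for pos, strand in occ}
    )
    instances: list[dict] = []  # {'start','end','kmers': {canon: offset_in_instance}, 'strand'}
    for pos, strand, km in seeds:
        if instances and pos - instances[-1]["end"] <= min_len and pos + k > instances[-1]["start"]:
            inst = instances[-1]
            inst["end"] = max(inst["end"], pos + k)
            inst["kmers"].setdefault(km, (pos, strand))
        else:
            instances.append({"start": pos, "end": pos + k, "kmers": {km: (pos, strand)}})

    # transitive clustering of instances sharing any seed
    parent = list(range(len(instances)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[str, int] = {}
    for idx, inst in enumerate(instances):
        for km in inst["kmers"]:
            if km in owner:
                ra, rb = find(owner[km]), find(idx)
                if ra != rb:
                    parent[ra] = rb
            else:
                owner[km] = idx

    groups: dict[int, list[int]] = {}
    for idx in range(len(instances)):
        groups.setdefault(find(idx), []).append(idx)

    clusters = []
    n_cluster = 0
    pad = 20  # extension allowance beyond the exact-seed span
    for members in sorted(groups.values(), key=lambda ms: instances[ms[0]]["start"]):
        if len(members) < min_copies:
            continue
        rep_idx = max(members, key=lambda i: instances[i]["end"] - instances[i]["start"])
        rep = instances[rep_idx]
        rep_len = rep["end"] - rep["start"]
        # anchor every instance to the representative's frame via shared
        # seeds, propagating transitively: an instance may share no seed
        # with the representative itself, only with other members
        frames: dict[int, tuple[int, str]] = {rep_idx: (rep["start"], "+")}
        pending = [i for i in members if i != rep_idx]
        progress = True
        while pending and progress:
            progress = False
            for idx in list(pending):
                inst = instances[idx]
                for src, (src_start, src_strand) in list(frames.items()):
                    if src_strand != "+":
                        continue
                    shared = set(inst["kmers"]) & set(instances[src]["kmers"])
                    if not shared:
                        continue
                    km = sorted(shared)[0]
                    ipos, istrand = inst["kmers"][km]
                    spos, sstrand = instances[src]["kmers"][km]
                    if istrand == sstrand:
                        frames[idx] = (ipos - (spos - src_start), "+")
                    else:
                        frames[idx] = (
                            ipos + k - (src_start + rep_len - spos), "-"
                        )
                    pending.remove(idx)
                    progress = True
                    break
        anchored = list(frames.values())
        if len(anchored) < min_copies:
            continue
        width = rep_len + 2 * pad
        stack = []
        for start, strand in sorted(set(anchored)):
            lo = start - pad
            seq = genome.sequence[max(0, lo) : max(0, lo) + width]
            seq = "N" * max(0, -lo) + seq
            seq = seq + "N" * (width - len(seq))
            stack.append((start, strand, seq if strand == "+" else reverse_complement(seq)))
        n_inst = len(stack)
        # column conservation (majority fraction) smoothed over 5 columns;
        # the element is the conserved run covering the seed span's centre
        cons = []
        for c in range(width):
            col = [s[2][c] for s in stack]
            best = max(col.count(b) for b in "ACGT")
            cons.append(best / n_inst)
        # X-drop extension from the seed-span centre: accumulate
        # (conservation - tau) outward and stop once the running sum falls
        # X below its maximum; the boundary is the argmax.  This walks over
        # isolated mutated columns but not into the unconserved flanks.
        centre = pad + rep_len // 2
        if cons[centre] < 0.5:
            continue
        # with only two copies a flank column matches by chance 1/4 of the
        # time, so the walk gets a lower bar but a much shorter leash
        tau, xdrop = (0.7, 0.35) if n_inst == 2 else (0.8, 1.5)
        lo = hi = centre
        for direction in (-1, 1):
            s = best = 0.0
            best_pos = centre
            c = centre + direction
            while 0 <= c < width:
                s += cons[c] - tau
                if s > best:
                    best, best_pos = s, c
                if s < best - xdrop:
                    break
                c += direction
            if direction < 0:
                lo = best_pos
            else:
                hi = best_pos
        element_len = hi - lo + 1
        if element_len < min_len:
            continue
        consensus = "".join(
            max("ACGT", key=lambda b: [s[2][c] for s in stack].count(b))
            for c in range(lo, hi + 1)
        )
        out = []
        for start, strand, seq in stack:
            sub = seq[lo : hi + 1]
            if _identity_at_offset(consensus, sub, 0) < min_identity:
                continue
            if strand == "+":
                g_start = start - pad + lo
                g_end = g_start + element_len
            else:
                g_end = start - pad + width - lo
                g_start = g_end - element_len
            g_start = max(0, g_start)
            g_end = min(len(genome), g_end)
            out.append((genome.genome_id, g_start, g_end, strand, sub.strip("N")))
        out = sorted(set(out), key=lambda t: t[1])
        if len(out) >= min_copies:
            n_cluster += 1
            clusters.append(
                RepeatCluster(
                    cluster_id=f"{genome.genome_id}_rep{n_cluster:02d}",
                    instances=out,
                    element_length=element_len,
                )
            )
    return clusters


def merge_repeats_across_genomes(
    per_genome_clusters: list[list[RepeatCluster]],
    min_identity: float = 0.8,
) -> list[RepeatCluster]:
    """Merge clusters from different genomes whose representative sequences
    match at >= min_identity (either strand, best ungapped offset)."""
    flat = [c for clusters in per_genome_clusters for c in clusters]
    if not flat:
        return []
    parent = list(range(len(flat)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def _merge_identity(a: str, b: str) -> float:
        # identity over the shorter element at the best ungapped offset;
        # per-genome boundary calls may carry a few bases of flank overhang
        short = min(len(a), len(b))
        best = 0.0
        for off in range(-(abs(len(a) - len(b)) + 5), abs(len(a) - len(b)) + 6):
            start_a, start_b = max(0, off), max(0, -off)
            n = min(len(a) - start_a, len(b) - start_b)
            if n < 0.7 * short:
                continue
            same = sum(a[start_a + i] == b[start_b + i] for i in range(n))
            best = max(best, same / short)
        return best

    reps = [c.representative() for c in flat]
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            fwd = _merge_identity(reps[i], reps[j])
            rev = _merge_identity(reps[i], reverse_complement(reps[j]))
            if max(fwd, rev) >= min_identity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for n, members in enumerate(sorted(groups.values(), key=lambda ms: ms[0]), start=1):
        instances = [inst for i in members for inst in flat[i].instances]
        # harmonise to the modal element length: per-genome boundary calls
        # can overshoot by a few bases, which would break the joint consensus
        lengths = [len(inst[4]) for inst in instances]
        top = max(lengths.count(l) for l in set(lengths))
        target = min(l for l in set(lengths) if lengths.count(l) == top)
        rep = next(inst[4] for inst in instances if len(inst[4]) == target)
        fixed = []
        for gid, s, e, strand, seq in instances:
            if len(seq) > target:
                off = max(
                    range(len(seq) - target + 1),
                    key=lambda o: sum(a == b for a, b in zip(rep, seq[o : o + target])),
                )
                seq = seq[off : off + target]
                if strand == "+":
                    s, e = s + off, s + off + target
                else:
                    s, e = e - off - target, e - off
            fixed.append((gid, s, e, strand, seq))
        fixed.sort(key=lambda t: (t[0], t[1]))
        merged.append(
            RepeatCluster(
                cluster_id=f"merged_rep{n:02d}",
                instances=fixed,
                element_length=target,
            )
        )
    return merged


def consensus_profile(cluster: RepeatCluster) -> ConsensusProfile:
    """Ungapped per-position base counts and consensus of a repeat cluster.

    Instances are stacked at their best offset against the longest instance;
    length differences beyond 2 nt are irreconcilable.
    """
    if cluster.n_instances < 2:
        raise ValueError("consensus needs at least two instances")
    ref = cluster.representative()
    length = len(ref)
    bad = [inst for inst in cluster.instances if abs(len(inst[4]) - length) > 2]
    if bad:
        raise ValueError(f"irreconcilable instance lengths: {[b[:4] for b in bad]}")
    counts = {b: [0] * length for b in "ACGT"}
    n_at = [0] * length
    for inst in cluster.instances:
        seq = inst[4]
        off, _ = _best_offset(ref, seq, max_shift=2)
        for i, base in enumerate(seq):
            pos = off + i
            if 0 <= pos < length and base in counts:
                counts[base][pos] += 1
                n_at[pos] += 1
    consensus = []
    strict = 0
    for pos in range(length):
        col = {b: counts[b][pos] for b in "ACGT"}
        best = max(col, key=lambda b: (col[b], b))
        if n_at[pos] and col[best] == cluster.n_instances:
            consensus.append(best)
            strict += 1
        else:
            consensus.append(best.lower() if n_at[pos] else "n")
    return ConsensusProfile(
        counts=counts,
        consensus="".join(consensus),
        strictly_conserved_count=strict,
    )


def scan_sigma70(
    sequence: str,
    genome_id: str = "",
    max_mm35: int = 1,
    max_mm10: int = 1,
    spacer_range: tuple[int, int] = (15, 19),
) -> list[Sigma70Hit]:
    """Sliding scan for sigma70 promoters (-35 TTGACA, -10 TATAAT) on both
    strands, with per-box mismatch allowances and a bounded spacer."""
    sequence = sequence.upper()
    lo, hi = spacer_range
    hits = []
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        n = len(seq)
        for i in range(n - 12 - lo + 1):
            box35 = seq[i : i + 6]
            mm35 = _hamming(box35, MINUS35)
            if mm35 > max_mm35:
                continue
            for spacer in range(lo, hi + 1):
                j = i + 6 + spacer
                if j + 6 > n:
                    break
                box10 = seq[j : j + 6]
                mm10 = _hamming(box10, MINUS10)
                if mm10 > max_mm10:
                    continue
                span = 12 + spacer
                start = i if strand == "+" else n - (i + span)
                hits.append(
                    Sigma70Hit(
                        genome_id=genome_id,
                        start=start,
                        strand=strand,
                        minus35=box35,
                        spacer_length=spacer,
                        minus10=box10,
                        mismatches=(mm35, mm10),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.spacer_length))
    return hits
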