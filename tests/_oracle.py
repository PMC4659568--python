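"""Independent brute-force oracle for the stepwise cascade.

Deliberately avoids the package's MatchKey/keys_agree machinery: candidate
sets are computed by direct field-by-field comparison over all trial x
admin pairs, and the unique/no-match/multiple classification plus
carry-forward is re-derived from first principles. Used to cross-check the
production implementation record-for-record on small instances.
"""

from __future__ import annotations


def _event(rec):
    d = rec.transfer_date if rec.transfer_date is not None else rec.enrollment_date
    return d


def _fields_complete(rec):
    return rec.gender is not None and rec.birth_year is not None and rec.birth_month is not None


def _pair_agrees(trial_rec, admin_rec, step) -> bool:
    if not _fields_complete(trial_rec) or not _fields_complete(admin_rec):
        return False
    if trial_rec.site_id != admin_rec.site_id:
        return False
    if trial_rec.gender != admin_rec.gender:
        return False
    if trial_rec.birth_year != admin_rec.birth_year:
        return False
    if trial_rec.birth_month != admin_rec.birth_month:
        return False
    ty, tm = _event(trial_rec).year, _event(trial_rec).month
    ay, am = admin_rec.admission_date.year, admin_rec.admission_date.month
    if step.year_mode.value == "EXACT" and ty != ay:
        return False
    if step.year_mode.value == "TOLERANCE" and abs(ty - ay) > step.year_tolerance:
        return False
    if step.month_mode.value == "EXACT" and tm != am:
        return False
    return True


def oracle_stepwise(trial, admin, steps):
    """Return (per-step classification dicts, final assignment dict)."""
    remaining_t = list(trial)
    remaining_a = list(admin)
    per_step = []
    final = {}
    for step in steps:
        cands = {
            t.trial_id: sorted(
                a.admin_id for a in remaining_a if _pair_agrees(t, a, step)
            )
            for t in remaining_t
        }
        classes = {}
        for tid, cc in cands.items():
            if len(cc) == 0:
                classes[tid] = "NO_MATCH"
            elif len(cc) > 1:
                classes[tid] = "MULTIPLE_ADMIN"
        claimed = {}
        for tid, cc in cands.items():
            if len(cc) == 1:
                claimed.setdefault(cc[0], []).append(tid)
        assignments = {}
        for aid, tids in claimed.items():
            if len(tids) == 1:
                classes[tids[0]] = "UNIQUE"
                assignments[tids[0]] = aid
            else:
                for tid in tids:
                    classes[tid] = "MULTIPLE_TRIAL"
        per_step.append(classes)
        final.update(assignments)
        gone_a = set(assignments.values())
        remaining_t = [t for t in remaining_t if t.trial_id not in assignments]
        remaining_a = [a for a in remaining_a if a.admin_id not in gone_a]
    return per_step, final
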