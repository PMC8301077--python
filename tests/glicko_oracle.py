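"""Independent straight-line transcription of the Glicko-1 update equations.

Kept deliberately separate from the package engine: no shared code, plain
loops, used only to cross-check one rating period.
"""

import math

Q = math.log(10) / 400


def oracle_one_period(ratings, rds, games):
    """One simultaneous rating period.

    ratings, rds: dicts keyed by player.
    games: list of (player, opponent, score) with score 1.0 or 0.0; each
    contest must appear once per participant (i.e., both directions).
    Returns (new_ratings, new_rds); players with no games are unchanged.
    """
    new_r = {}
    new_rd = {}
    for p in ratings:
        my_games = [(o, s) for (pl, o, s) in games if pl == p]
        if not my_games:
            new_r[p] = ratings[p]
            new_rd[p] = rds[p]
            continue
        d2_inv = 0.0
        acc = 0.0
        for opp, score in my_games:
            g_j = 1 / math.sqrt(1 + 3 * Q * Q * rds[opp] ** 2 / math.pi**2)
            e_j = 1 / (1 + 10 ** (-g_j * (ratings[p] - ratings[opp]) / 400))
            d2_inv += Q * Q * g_j * g_j * e_j * (1 - e_j)
            acc += g_j * (score - e_j)
        d2 = 1 / d2_inv
        denom = 1 / rds[p] ** 2 + 1 / d2
        new_r[p] = ratings[p] + (Q / denom) * acc
        new_rd[p] = math.sqrt(1 / denom)
    return new_r, new_rd
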