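"""Straightforward reference simulator for scripted, randomness-free runs.

A deliberately simple, dict-based transcription of the hourly rules,
kept independent of the package's engine so the two can be compared
trace-for-trace on small scripted scenarios.  Only deterministic inputs
are supported: bugs are injected by an explicit spawn schedule, never by
chance, and they do not move.
"""

from math import inf


def simulate_reference(config, spawns, strategy_name):
    """Return a list of per-hour metric tuples.

    Each tuple is (iteration, avg_power, crop_health_pct, alive_bugs_pct,
    pesticide_per_station, messages_this_hour, active_stations,
    alive_bugs), matching the engine's record fields.

    ``spawns`` is an iterable of (hour, (x, y), count).
    """
    m, n = config.columns, config.rows
    d = config.fumigation_window
    q = config.pesticide_per_fumigation
    e_msg = config.energy_per_message
    h_die = config.exposure_hours_to_die

    cells = [(x, y) for x in range(m) for y in range(n)]
    health = {c: 100.0 for c in cells}
    pesticide = {c: 0.0 for c in cells}
    fum_now: set = set()
    bugs = []  # dicts: pos, exposure, alive
    last_warn = {c: {(i, j): -inf for i in range(3) for j in range(3)} for c in cells}
    last_detect = {c: -inf for c in cells}
    power_samples = []
    records = []

    def neighbors(cell):
        x, y = cell
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if (dx, dy) == (0, 0):
                    continue
                if 0 <= x + dx < m and 0 <= y + dy < n:
                    out.append((x + dx, y + dy))
        return out

    for t in range(config.hours):
        fum_prev = fum_now
        fum_now = set()
        messages = 0
        active: set = set()

        for hour, pos, count in spawns:
            if hour == t:
                for _ in range(count):
                    bugs.append({"pos": tuple(pos), "exposure": 0, "alive": True})

        def fumigate(cell):
            active.add(cell)
            if cell not in fum_now:
                fum_now.add(cell)
                pesticide[cell] += q

        def receive(sender, target):
            # reactive rule of each strategy
            fumigate(target)
            if strategy_name == "lowcost_neighbor":
                local = (sender[0] - target[0] + 1, sender[1] - target[1] + 1)
                last_warn[target][local] = t

        def send(sender, target):
            nonlocal messages
            messages += 1
            active.add(sender)
            receive(sender, target)

        def has_alive_bugs(cell):
            return any(b["alive"] and b["pos"] == cell for b in bugs)

        # periodic hooks, raster order
        for y in range(n):
            for x in range(m):
                cell = (x, y)
                if strategy_name == "broadcast":
                    if has_alive_bugs(cell):
                        fumigate(cell)
                        for other in cells:
                            if other != cell:
                                send(cell, other)
                elif strategy_name == "neighbor":
                    if has_alive_bugs(cell):
                        fumigate(cell)
                        for nbr in neighbors(cell):
                            send(cell, nbr)
                elif strategy_name == "lowcost_neighbor":
                    if has_alive_bugs(cell) and t - last_detect[cell] > d:
                        for nbr in neighbors(cell):
                            local = (nbr[0] - cell[0] + 1, nbr[1] - cell[1] + 1)
                            if t - last_warn[cell][local] > d:
                                send(cell, nbr)
                        last_detect[cell] = t
                    if t - last_detect[cell] <= d:
                        fumigate(cell)
                else:
                    raise ValueError(strategy_name)

        # exposure and death
        for b in bugs:
            if b["alive"] and b["pos"] in fum_now:
                b["exposure"] += 1
                if b["exposure"] >= h_die:
                    b["alive"] = False

        # eating (blocked only by previous-hour fumigation)
        for b in bugs:
            if b["alive"] and b["pos"] not in fum_prev:
                health[b["pos"]] = max(0.0, health[b["pos"]] - config.eat_rate)

        # regrowth
        for c in cells:
            health[c] = min(100.0, health[c] + config.grow_rate)

        # metrics
        if active:
            power_samples.append(messages * e_msg / len(active))
        alive = sum(1 for b in bugs if b["alive"])
        total = len(bugs)
        records.append(
            (
                t,
                sum(power_samples) / len(power_samples) if power_samples else 0.0,
                sum(health.values()) / len(cells),
                100.0 if total == 0 else 100.0 * alive / total,
                sum(pesticide.values()) / len(cells),
                messages,
                len(active),
                alive,
            )
        )
    return records
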