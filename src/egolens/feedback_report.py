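"""Interactive two-tab feedback report.

Assembles the metric outputs into a JSON-serialisable payload organised
around the clinical questions a social-context feedback should answer,
then renders it as a single self-contained HTML document ("Network &
Relationships" and "Daily Interactions" tabs) with no external assets:
the payload is embedded as JSON and small hand-written JS/SVG views
draw the charts. Rendering is a pure view — every number shown comes
from a payload field, and identical payloads yield identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .core_model import ROLES, ParticipantDataset
from .network_reconciliation import reconcile
from .social_metrics import (
    affect_timeline,
    interaction_counts,
    interaction_detail,
    known_affect_items,
    known_indicators,
    network_structure,
    perception_behavior_table,
    quality_summary,
    role_composition,
    word_frequencies,
)

SECTIONS = (
    "network_composition",   # role bar charts, pre/post
    "sociograms",            # node-link drawings with ties
    "membership_change",     # added / removed / stable colouring
    "alter_table",           # demographics + dichotomous ratings
    "counts_quality",        # counts and quality per role / partner
    "timeline",              # affect line + interaction points
    "wordcloud",             # content term frequencies
)

#: The clinical questions the report must answer, with the sections able
#: to answer each. Grouped by data source: network assessment (PSN),
#: interaction diary (ESM), and their combination.
QUESTIONS: dict[str, dict] = {
    "q01": {"text": "How many network members does the participant have?",
            "group": "psn", "sections": ["network_composition", "alter_table"]},
    "q02": {"text": "Does the network change over the course of the assessment period or intervention?",
            "group": "psn", "sections": ["sociograms", "membership_change"]},
    "q03": {"text": "Does the participant have (emotional/practical) support resources?",
            "group": "psn", "sections": ["alter_table"]},
    "q04": {"text": "How does the participant perceive social relationships?",
            "group": "psn", "sections": ["alter_table"]},
    "q05": {"text": "How socially active is the participant in daily life?",
            "group": "esm", "sections": ["counts_quality"]},
    "q06": {"text": "Of what quality are the social interactions of the participant?",
            "group": "esm", "sections": ["counts_quality", "wordcloud"]},
    "q07": {"text": "To what extent are social interactions related to mood or other symptoms?",
            "group": "esm", "sections": ["timeline"]},
    "q08": {"text": "Are there particularly impactful social interactions? If so, what happened during these?",
            "group": "esm", "sections": ["timeline"]},
    "q09": {"text": "Does the participant use available social resources in daily life?",
            "group": "psn+esm", "sections": ["counts_quality"]},
    "q10": {"text": "With which network members does the participant interact?",
            "group": "psn+esm", "sections": ["counts_quality"]},
    "q11": {"text": "Social interactions with which network members are perceived particularly positively or negatively?",
            "group": "psn+esm", "sections": ["counts_quality", "timeline"]},
    "q12": {"text": "Does the participant's overall perception of a relationship match what is happening in daily life?",
            "group": "psn+esm", "sections": ["alter_table", "counts_quality"]},
}

_LAYOUT_SEED = 42


@dataclass
class ReportOptions:
    indicator: Optional[str] = None  # default: first indicator in the data
    affect_item: Optional[str] = None  # default: first affect item
    partner_filter: Optional[list[str]] = None
    simple_mode: bool = False
    anonymisation_mode: str = "real_names"
    annotations: dict[str, str] = field(default_factory=dict)  # section -> free text


@dataclass
class ReportPayload:
    participant_id: str
    options: dict
    sections: dict[str, dict]
    questions: dict[str, dict]

    def section(self, name: str) -> dict:
        return self.sections[name]

    def to_json(self) -> str:
        return json.dumps(
            {
                "participant_id": self.participant_id,
                "options": self.options,
                "sections": self.sections,
                "questions": self.questions,
            },
            sort_keys=True, ensure_ascii=False, separators=(",", ":"),
        )


def _iso(dt) -> Optional[str]:
    return dt.isoformat() if dt is not None else None


def _py(v):
    """Coerce numpy scalars / NaN to JSON-native values."""
    import numpy as np

    if isinstance(v, (np.bool_, bool)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return None if f != f else f
    return v


def _sociogram_data(wave, status: Optional[dict[str, str]]) -> dict:
    g = nx.Graph()
    g.add_nodes_from(a.alter_id for a in wave.alters)
    g.add_edges_from(t for t in wave.ties if t[0] != t[1])
    pos = nx.spring_layout(g, seed=_LAYOUT_SEED) if g.number_of_nodes() else {}
    return {
        "label": wave.label,
        "date": wave.date.isoformat() if wave.date else None,
        "nodes": [
            {
                "id": a.alter_id,
                "name": a.display_name,
                "role": a.role,
                "status": (status or {}).get(a.alter_id, "stable"),
                "x": round(float(pos[a.alter_id][0]), 4),
                "y": round(float(pos[a.alter_id][1]), 4),
            }
            for a in wave.alters
        ],
        "edges": [list(t) for t in wave.ties],
    }


def _empty(reason: str, questions: list[str]) -> dict:
    return {"available": False, "reason": reason, "questions": questions, "data": None}


def build_payload(dataset: ParticipantDataset, options: Optional[ReportOptions] = None) -> ReportPayload:
    """Compute every report section from the dataset.

    All numbers come from the metric and reconciliation operations —
    nothing is computed at render time. With a single network wave the
    change-dependent sections degrade gracefully (marked unavailable
    with a reason) and drop their claim on the network-change question.
    """
    opts = options or ReportOptions()
    pre = dataset.wave("pre")
    post = dataset.wave("post")
    waves = [w for w in (pre, post) if w is not None]
    if not waves:
        raise ValueError("dataset has no network wave")
    latest = waves[-1]
    two_waves = pre is not None and post is not None

    indicators = known_indicators(dataset.events)
    affect_items = known_affect_items(dataset.responses, dataset.events)
    indicator = opts.indicator or (indicators[0] if indicators else None)
    affect_item = opts.affect_item or (affect_items[0] if affect_items else None)
    if indicator is not None and indicators and indicator not in indicators:
        raise KeyError(f"unknown quality indicator {indicator!r}")
    if affect_item is not None and affect_items and affect_item not in affect_items:
        raise KeyError(f"unknown affect item {affect_item!r}")

    esm_roster = [a for a in dataset.roster if a.origin == "esm"]
    recon = reconcile(pre, post, esm_roster) if two_waves else None
    status = recon.status if recon else None
    names = {a.alter_id: a.display_name for a in dataset.roster}

    sections: dict[str, dict] = {}

    sections["network_composition"] = {
        "available": True, "reason": None,
        "questions": ["q01"],
        "data": {
            "roles": list(ROLES),
            "waves": {w.label: role_composition(w) for w in waves},
        },
    }

    soc = {
        "waves": [_sociogram_data(w, status) for w in waves],
        "structure": {
            w.label: {
                "isolates": network_structure(w).isolates,
                "components": network_structure(w).components,
            }
            for w in waves
        },
        "comparable": two_waves,
    }
    sections["sociograms"] = {
        "available": True, "reason": None,
        "questions": ["q02"] if two_waves else [],
        "data": soc,
    }

    if recon is not None:
        sections["membership_change"] = {
            "available": True, "reason": None,
            "questions": ["q02"],
            "data": {
                "counts": recon.counts(),
                "status": dict(sorted(recon.status.items())),
                "role_changes": [list(rc) for rc in recon.role_changes],
                "rating_deltas": recon.rating_deltas,
                "flag_flips": recon.flag_flips,
                "warnings": recon.warnings,
            },
        }
    else:
        sections["membership_change"] = _empty(
            "requires both a pre- and a post-ESM network assessment", ["q02"]
        )
        sections["membership_change"]["questions"] = []

    table = perception_behavior_table(latest, dataset.events)
    table = table.sort_values(["closeness", "alter_id"], ascending=[False, True], na_position="last")
    sections["alter_table"] = {
        "available": True, "reason": None,
        "questions": ["q01", "q03", "q04", "q12"],
        "data": {
            "wave": latest.label,
            "flag_names": sorted({f for a in latest.alters for f in a.flags}),
            "rows": [
                {k: _py(v) for k, v in row.items()}
                for row in table.to_dict(orient="records")
            ],
        },
    }

    has_events = bool(dataset.events)
    if has_events:
        by_role_counts = interaction_counts(dataset.events, dataset.roster, by="role")
        by_partner_counts = interaction_counts(dataset.events, dataset.roster, by="partner")
        quality = {
            ind: {
                grouping: [
                    {
                        "group": s.group_key,
                        "label": names.get(s.group_key, s.group_key) if grouping == "partner" else s.group_key,
                        "n": s.n,
                        "points": s.points,
                        "mean": round(s.mean, 4),
                        "ci_low": None if s.ci_low is None else round(s.ci_low, 4),
                        "ci_high": None if s.ci_high is None else round(s.ci_high, 4),
                    }
                    for s in quality_summary(dataset.events, dataset.roster, by=grouping, indicator=ind)
                ]
                for grouping in ("role", "partner")
            }
            for ind in indicators
        }
        sections["counts_quality"] = {
            "available": True, "reason": None,
            "questions": ["q05", "q06", "q09", "q10", "q11", "q12"],
            "data": {
                "counts_by_role": by_role_counts,
                "counts_by_partner": [
                    {"id": aid, "label": names.get(aid, aid), "count": c}
                    for aid, c in sorted(by_partner_counts.items(), key=lambda kv: (-kv[1], kv[0]))
                ],
                "indicators": indicators,
                "quality": quality,
            },
        }
    else:
        sections["counts_quality"] = _empty("no interaction events logged",
                                            ["q05", "q06", "q09", "q10", "q11", "q12"])
        sections["counts_quality"]["questions"] = []

    if dataset.responses or has_events:
        pf = set(opts.partner_filter) if opts.partner_filter else None
        timelines = {}
        for item in affect_items or ([affect_item] if affect_item else []):
            tl = affect_timeline(
                dataset.responses, dataset.events,
                affect_item=item, indicator=indicator or (indicators[0] if indicators else "meaningfulness"),
                partner_filter=pf, roster=dataset.roster,
            )
            timelines[item] = [
                {"time": _iso(p.time), "value": p.value, "source": p.source}
                for p in tl.affect_series
            ]
        event_points = {}
        for ind in indicators:
            tl = affect_timeline(
                dataset.responses, dataset.events,
                affect_item=affect_item or (affect_items[0] if affect_items else "happiness"),
                indicator=ind, partner_filter=pf, roster=dataset.roster,
            )
            event_points[ind] = [
                {
                    "time": _iso(p.time), "value": p.value, "role": p.role,
                    "is_group": p.is_group, "partner_ids": p.partner_ids,
                    "event_id": p.event_id,
                }
                for p in tl.event_points
            ]
        details = {}
        for e in dataset.events:
            d = interaction_detail(dataset.events, e.event_id, dataset.roster)
            d["start_time"] = _iso(d["start_time"])
            details[e.event_id] = d
        sections["timeline"] = {
            "available": True, "reason": None,
            "questions": ["q07", "q08", "q11"],
            "data": {
                "affect_items": affect_items,
                "affect_series": timelines,
                "event_points": event_points,
                "details": details,
                "partners": [
                    {"id": a.alter_id, "label": a.display_name} for a in dataset.roster
                ],
            },
        }
    else:
        sections["timeline"] = _empty("no momentary assessments collected", ["q07", "q08", "q11"])
        sections["timeline"]["questions"] = []

    terms = word_frequencies(dataset.events)
    if terms:
        sections["wordcloud"] = {
            "available": True, "reason": None,
            "questions": ["q06"],
            "data": {"terms": [[t, c] for t, c in terms[:100]]},
        }
    else:
        sections["wordcloud"] = _empty("no interaction descriptions to summarise", ["q06"])
        sections["wordcloud"]["questions"] = []

    questions = {
        qid: {
            "text": q["text"],
            "group": q["group"],
            "sections": q["sections"],
        }
        for qid, q in QUESTIONS.items()
    }
    return ReportPayload(
        participant_id=dataset.participant_id,
        options={
            "indicator": indicator,
            "affect_item": affect_item,
            "partner_filter": opts.partner_filter,
            "simple_mode": opts.simple_mode,
            "anonymisation_mode": opts.anonymisation_mode,
            "annotations": dict(opts.annotations),
        },
        sections=sections,
        questions=questions,
    )


def coverage_check(payload: ReportPayload) -> list[str]:
    """Clinical questions not answered by any populated section.

    ``q02`` (network change) is special-cased through the sociogram
    section's dynamic claim: with one wave there is nothing to compare,
    so only the membership-change claim could cover it. Returns the
    sorted ids of unanswered questions; empty means full coverage.
    """
    claimed: set[str] = set()
    for sec in payload.sections.values():
        if sec["available"]:
            claimed.update(sec["questions"])
    return sorted(qid for qid in payload.questions if qid not in claimed)


# --------------------------------------------------------------------- HTML

def render_report(payload: ReportPayload, destination) -> Path:
    """Write the payload as one self-contained interactive HTML file."""
    dest = Path(destination)
    html = _TEMPLATE.replace("/*__PAYLOAD__*/null", payload.to_json())
    dest.write_text(html, encoding="utf-8")
    return dest


_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Social context feedback report</title>
<style>
 body{font-family:system-ui,sans-serif;margin:0;background:#f6f7f9;color:#222}
 header{background:#274060;color:#fff;padding:0.8rem 1.2rem}
 nav button{font-size:1rem;padding:0.5rem 1.2rem;margin-right:0.4rem;border:0;cursor:pointer;
            border-radius:6px 6px 0 0;background:#d7dde5}
 nav button.active{background:#fff;font-weight:600}
 .tab{display:none;padding:1rem 1.5rem}
 .tab.visible{display:block}
 section{background:#fff;border-radius:8px;padding:1rem 1.2rem;margin-bottom:1.2rem;
         box-shadow:0 1px 3px rgba(0,0,0,.08)}
 h2{margin-top:0;font-size:1.05rem}
 table{border-collapse:collapse;font-size:0.85rem}
 th,td{border:1px solid #ccd;padding:2px 8px;text-align:left}
 .controls{margin:0.4rem 0}
 .controls label{margin-right:1rem}
 svg text{font-size:10px}
 .note{color:#666;font-size:0.8rem}
 .annotation{background:#fffbe6;border-left:3px solid #e6c200;padding:0.4rem 0.8rem;
             margin:0.5rem 0;font-size:0.85rem}
 #detail{border:1px dashed #99a;padding:0.6rem;margin-top:0.6rem;font-size:0.85rem}
</style>
</head>
<body>
<header><strong>Social context feedback</strong> — participant <span id="pid"></span></header>
<nav style="padding:0.6rem 1.2rem 0">
 <button id="btn-network" class="active" onclick="showTab('network')">Network &amp; Relationships</button>
 <button id="btn-interactions" onclick="showTab('interactions')">Daily Interactions</button>
</nav>
<div id="tab-network" class="tab visible">
 <section id="sec-network_composition"><h2>Network composition by social role</h2><div class="body"></div></section>
 <section id="sec-sociograms"><h2>Personal network (who knows whom)</h2><div class="body"></div></section>
 <section id="sec-membership_change"><h2>Network change: members added and removed</h2><div class="body"></div></section>
 <section id="sec-alter_table"><h2>Network members and relationship ratings</h2><div class="body"></div></section>
</div>
<div id="tab-interactions" class="tab">
 <section id="sec-counts_quality"><h2>Quantity and quality of social interactions</h2>
  <div class="controls"><label>Quality indicator
   <select id="indicator-select" onchange="renderCounts()"></select></label></div>
  <div class="body"></div></section>
 <section id="sec-timeline"><h2>Affect and interactions over the study period</h2>
  <div class="controls">
   <label>Affect <select id="affect-select" onchange="renderTimeline()"></select></label>
   <label>Indicator <select id="tl-indicator-select" onchange="renderTimeline()"></select></label>
   <label>Partner filter <select id="partner-select" onchange="renderTimeline()"><option value="">(all)</option></select></label>
   <label><input type="checkbox" id="simple-toggle" onchange="renderTimeline()"> simple view</label>
  </div>
  <div class="body"></div><div id="detail" class="note">Click an interaction point for details.</div></section>
 <section id="sec-wordcloud"><h2>What interactions were about</h2><div class="body"></div></section>
</div>
<script type="application/json" id="payload">/*__PAYLOAD__*/null</script>
<script>
const P = JSON.parse(document.getElementById('payload').textContent);
const ROLE_COLOURS = {family:'#3b6fb6', friend:'#43a047', romantic_partner:'#d81b60',
  fellow_student_or_colleague:'#f9a825', acquaintance:'#8d6e63', other:'#78909c'};
const STATUS_COLOURS = {stable:'#888', removed:'#d32f2f', added_during_esm:'#1e88e5', added_post:'#8e24aa'};
document.getElementById('pid').textContent = P.participant_id;

function showTab(which){
  for(const t of ['network','interactions']){
    document.getElementById('tab-'+t).classList.toggle('visible', t===which);
    document.getElementById('btn-'+t).classList.toggle('active', t===which);
  }
}
function el(tag, attrs, text){
  const ns = 'http://www.w3.org/2000/svg';
  const e = ['svg','rect','circle','line','text','g','polyline'].includes(tag)
    ? document.createElementNS(ns, tag) : document.createElement(tag);
  for(const k in (attrs||{})) e.setAttribute(k, attrs[k]);
  if(text!==undefined) e.textContent = text;
  return e;
}
function sectionBody(name){
  const sec = document.getElementById('sec-'+name);
  const body = sec.querySelector('.body');
  body.textContent = '';
  const ann = P.options.annotations && P.options.annotations[name];
  if(ann){ const d = el('div',{class:'annotation'}); d.textContent = ann; body.appendChild(d); }
  const data = P.sections[name];
  if(!data.available){
    const n = el('p',{class:'note'}); n.textContent = 'Not available: ' + data.reason;
    body.appendChild(n); return null;
  }
  return body;
}
function barChart(entries, colourOf, width){
  width = width || 560;
  const max = Math.max(1, ...entries.map(e=>e.value));
  const rowH = 18, svg = el('svg',{width:width, height:entries.length*rowH+10});
  entries.forEach((e,i)=>{
    const w = (e.value/max)*(width-220);
    svg.appendChild(el('rect',{x:160,y:i*rowH+4,width:Math.max(w,1),height:rowH-6,fill:colourOf(e)}));
    svg.appendChild(el('text',{x:155,y:i*rowH+15,'text-anchor':'end'}, e.label));
    svg.appendChild(el('text',{x:165+w,y:i*rowH+15}, String(e.value)));
  });
  return svg;
}
function renderComposition(){
  const body = sectionBody('network_composition'); if(!body) return;
  const d = P.sections.network_composition.data;
  for(const wave in d.waves){
    body.appendChild(el('h3',{}, wave==='pre' ? 'Before the interaction diary' : 'After the interaction diary'));
    body.appendChild(barChart(d.roles.map(r=>({label:r.replace(/_/g,' '), value:d.waves[wave][r], role:r})),
                              e=>ROLE_COLOURS[e.role], 520));
  }
}
function sociogramSvg(w, colourBy){
  const size=340, pad=25, svg=el('svg',{width:size,height:size+14});
  const sx=v=>pad+(v+1)/2*(size-2*pad), sy=v=>pad+(1-(v+1)/2)*(size-2*pad);
  const pos={}; w.nodes.forEach(n=>pos[n.id]=n);
  w.edges.forEach(e=>{
    const a=pos[e[0]], b=pos[e[1]]; if(!a||!b) return;
    svg.appendChild(el('line',{x1:sx(a.x),y1:sy(a.y),x2:sx(b.x),y2:sy(b.y),stroke:'#bbb'}));
  });
  w.nodes.forEach(n=>{
    const c = colourBy==='status' ? STATUS_COLOURS[n.status] : ROLE_COLOURS[n.role];
    const g = el('g'); g.appendChild(el('circle',{cx:sx(n.x),cy:sy(n.y),r:6,fill:c}));
    const t = el('text',{x:sx(n.x)+7,y:sy(n.y)+3}, n.name); g.appendChild(t); svg.appendChild(g);
  });
  svg.appendChild(el('text',{x:6,y:size+8,'font-weight':'600'}, w.label==='pre'?'pre-ESM':'post-ESM'));
  return svg;
}
function renderSociograms(){
  const body = sectionBody('sociograms'); if(!body) return;
  const d = P.sections.sociograms.data;
  d.waves.forEach(w=>body.appendChild(sociogramSvg(w,'role')));
  const iso = d.structure[d.waves[d.waves.length-1].label].isolates;
  if(iso.length){const p=el('p',{class:'note'});p.textContent='Members not connected to anyone: '+iso.join(', ');body.appendChild(p);}
}
function renderMembership(){
  const body = sectionBody('membership_change'); if(!body) return;
  const d = P.sections.membership_change.data;
  const c = d.counts;
  const p = el('p'); p.textContent = `Stable: ${c.stable} · removed: ${c.removed} · `+
    `added during the diary: ${c.added_during_esm} · added at the post assessment: ${c.added_post}`;
  body.appendChild(p);
  const soc = P.sections.sociograms;
  if(soc.available){
    soc.data.waves.forEach(w=>body.appendChild(sociogramSvg(w,'status')));
  }
  if(d.role_changes.length){
    const h = el('p'); h.textContent = 'Role changes: ' +
      d.role_changes.map(r=>`${r[0]}: ${r[1].replace(/_/g,' ')} \\u2192 ${r[2].replace(/_/g,' ')}`).join('; ');
    body.appendChild(h);
  }
}
function renderAlterTable(){
  const body = sectionBody('alter_table'); if(!body) return;
  const d = P.sections.alter_table.data;
  const tbl = el('table'), head = el('tr');
  const cols = ['display_name','role','closeness'].concat(d.flag_names).concat(['n_interactions','mean_quality','discrepancy']);
  const titles = {display_name:'name', n_interactions:'# interactions', mean_quality:'mean quality',
                  discrepancy:'close but no contact?'};
  cols.forEach(cn=>head.appendChild(el('th',{}, (titles[cn]||cn).replace(/_/g,' '))));
  tbl.appendChild(head);
  d.rows.forEach(r=>{
    const tr = el('tr');
    cols.forEach(cn=>{
      let v = r[cn];
      if(typeof v === 'boolean') v = v ? '\\u2713' : '';
      if(v === null || v === undefined) v = '';
      if(typeof v === 'number' && cn==='mean_quality') v = v.toFixed(1);
      tr.appendChild(el('td',{}, String(v)));
    });
    tbl.appendChild(tr);
  });
  body.appendChild(tbl);
}
function dotCI(entries, width){
  width = width || 560;
  const rowH=18, svg=el('svg',{width:width,height:entries.length*rowH+20});
  const x=v=>180+(v/10)*(width-240);
  for(let g=0;g<=10;g+=2){
    svg.appendChild(el('line',{x1:x(g),y1:2,x2:x(g),y2:entries.length*rowH+2,stroke:'#eee'}));
    svg.appendChild(el('text',{x:x(g)-3,y:entries.length*rowH+14}, String(g)));
  }
  entries.forEach((e,i)=>{
    const cy=i*rowH+10;
    svg.appendChild(el('text',{x:175,y:cy+3,'text-anchor':'end'}, e.label+' (n='+e.n+')'));
    e.points.forEach(p=>svg.appendChild(el('circle',{cx:x(p),cy:cy,r:2.5,fill:e.colour,'fill-opacity':0.25})));
    if(e.ci_low!==null && e.ci_low!==undefined)
      svg.appendChild(el('line',{x1:x(e.ci_low),y1:cy,x2:x(e.ci_high),y2:cy,stroke:'#333','stroke-width':2}));
    svg.appendChild(el('circle',{cx:x(e.mean),cy:cy,r:5,fill:e.colour,stroke:'#222'}));
  });
  return svg;
}
function renderCounts(){
  const body = sectionBody('counts_quality'); if(!body) return;
  const d = P.sections.counts_quality.data;
  const sel = document.getElementById('indicator-select');
  if(!sel.options.length){
    d.indicators.forEach(ind=>{const o=el('option',{value:ind},ind);o.value=ind;sel.appendChild(o);});
    sel.value = P.options.indicator || d.indicators[0];
  }
  const ind = sel.value;
  body.appendChild(el('h3',{}, 'Number of interactions per social role'));
  body.appendChild(barChart(Object.entries(d.counts_by_role).map(([r,v])=>({label:r.replace(/_/g,' '),value:v,role:r})),
                            e=>ROLE_COLOURS[e.role], 520));
  body.appendChild(el('h3',{}, 'Number of interactions per network member'));
  const byP = d.counts_by_partner.filter(e=>e.count>0);
  body.appendChild(barChart(byP.map(e=>({label:e.label,value:e.count})), ()=>'#5b8db8', 520));
  const q = d.quality[ind];
  body.appendChild(el('h3',{}, 'Interaction quality ('+ind+') per social role — dot = mean, bar = 95% CI'));
  body.appendChild(dotCI(q.role.map(s=>({label:s.group.replace(/_/g,' '),n:s.n,points:s.points,mean:s.mean,
    ci_low:s.ci_low,ci_high:s.ci_high,colour:ROLE_COLOURS[s.group]||'#78909c'})), 620));
  body.appendChild(el('h3',{}, 'Interaction quality ('+ind+') per network member'));
  body.appendChild(dotCI(q.partner.map(s=>({label:s.label,n:s.n,points:s.points,mean:s.mean,
    ci_low:s.ci_low,ci_high:s.ci_high,colour:'#5b8db8'})), 620));
}
function renderTimeline(){
  const body = sectionBody('timeline'); if(!body) return;
  const d = P.sections.timeline.data;
  const aSel = document.getElementById('affect-select');
  const iSel = document.getElementById('tl-indicator-select');
  const pSel = document.getElementById('partner-select');
  if(!aSel.options.length){
    d.affect_items.forEach(it=>{const o=el('option');o.value=it;o.textContent=it;aSel.appendChild(o);});
    aSel.value = P.options.affect_item || d.affect_items[0];
    Object.keys(d.event_points).forEach(it=>{const o=el('option');o.value=it;o.textContent=it;iSel.appendChild(o);});
    iSel.value = P.options.indicator || Object.keys(d.event_points)[0];
    d.partners.forEach(pt=>{const o=el('option');o.value=pt.id;o.textContent=pt.label;pSel.appendChild(o);});
    document.getElementById('simple-toggle').checked = !!P.options.simple_mode;
  }
  const simple = document.getElementById('simple-toggle').checked;
  const filter = pSel.value;
  const series = d.affect_series[aSel.value]||[];
  let points = d.event_points[iSel.value]||[];
  if(filter) points = points.filter(p=>p.partner_ids.includes(filter));
  const W=860,H=220,pad=40;
  const times = series.map(s=>Date.parse(s.time)).concat(points.map(p=>Date.parse(p.time)));
  if(!times.length){body.appendChild(el('p',{class:'note'},'No timeline data.'));return;}
  const t0=Math.min(...times), t1=Math.max(...times)||t0+1;
  const X=t=>pad+(Date.parse(t)-t0)/(t1-t0||1)*(W-2*pad);
  const Y=v=>H-20-(v/10)*(H-40);
  const svg=el('svg',{width:W,height:H});
  for(let gr=0;gr<=10;gr+=5){
    svg.appendChild(el('line',{x1:pad,y1:Y(gr),x2:W-pad,y2:Y(gr),stroke:'#eee'}));
    svg.appendChild(el('text',{x:4,y:Y(gr)+3}, String(gr)));
  }
  const line = series.map(s=>X(s.time)+','+Y(s.value)).join(' ');
  svg.appendChild(el('polyline',{points:line,fill:'none',stroke:'#999','stroke-width':1.5}));
  points.forEach(p=>{
    const fill = simple ? '#444' : (ROLE_COLOURS[p.role]||'#78909c');
    const r = (!simple && p.is_group) ? 6 : 4;
    const c = el('circle',{cx:X(p.time),cy:Y(p.value),r:r,fill:fill,stroke:'#fff',cursor:'pointer'});
    c.addEventListener('click',()=>showDetail(p.event_id));
    svg.appendChild(c);
  });
  body.appendChild(svg);
  const legend = el('p',{class:'note'});
  legend.textContent = simple
    ? 'Grey line: ' + aSel.value + '. Dots: interactions (uniform encoding — simple view).'
    : 'Grey line: ' + aSel.value + '. Dot colour: social role of the first partner; large dots are group interactions.';
  body.appendChild(legend);
}
function showDetail(eventId){
  const d = P.sections.timeline.data.details[eventId];
  const box = document.getElementById('detail');
  box.textContent = '';
  const lines = [
    'When: '+d.start_time, 'With: '+d.partner_names.join(', '),
    'Mode: '+d.mode.replace(/_/g,' ')+' · '+d.duration_min+' min at '+d.location,
    'Type: '+d.category+(d.is_group?' (group)':''),
    'Quality: '+Object.entries(d.quality).map(([k,v])=>k+': '+v).join(', '),
    'About: '+d.content_text,
  ];
  lines.forEach(t=>{const pEl=el('div');pEl.textContent=t;box.appendChild(pEl);});
}
function renderWordcloud(){
  const body = sectionBody('wordcloud'); if(!body) return;
  const terms = P.sections.wordcloud.data.terms;
  const max = Math.max(1, ...terms.map(t=>t[1]));
  const div = el('div',{style:'line-height:2.2'});
  terms.forEach(([term,count])=>{
    const s = el('span',{style:'margin:0 8px;font-size:'+(10+22*count/max)+'px;color:#274060'},
                 term);
    s.title = count + ' mention(s)';
    div.appendChild(s);
  });
  body.appendChild(div);
}
renderComposition(); renderSociograms(); renderMembership(); renderAlterTable();
renderCounts(); renderTimeline(); renderWordcloud();
</script>
</body>
</html>
"""
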