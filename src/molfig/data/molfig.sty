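\NeedsTeXFormat{LaTeX2e}
\ProvidesPackage{molfig}[2026/09/24 v0.1 support macros for molfig-generated chemfig code]
\RequirePackage{chemfig}

% radical electron: a dot raised to superscript height
\newcommand*\mcfdot{\ensuremath{^{\bullet}}}

% small atom-number tag, printed beside the atom it annotates
\newcommand*\mcfatomno[1]{{\tiny\ensuremath{{}_{#1}}}}

% inscribed aromatic-ring circle; #1 is the radius in bond-length units,
% drawn here at 1em per unit (chemfig's default atom separation is ~3em,
% so tune \mcfcringleunit to taste)
\newlength\mcfcringleunit
\setlength\mcfcringleunit{1.7em}
\newcommand*\mcfcringle[1]{%
  \begin{tikzpicture}[baseline={(0,-0.5ex)}]%
    \draw (0,0) circle [radius=#1\mcfcringleunit];%
  \end{tikzpicture}}
\endinput
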